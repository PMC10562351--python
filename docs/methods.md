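# Methods

This note documents the modelling and design choices behind `fedaki`:
what each stage computes, which constants matter, what the synthetic
generator does and does not emulate, and the numerical conventions.

## KDIGO labeling

All windows are half-open `(start, end]`; times are decimal hours with
ICU admission at 0 and pre-admission records at negative times (up to
−168 h).

**Baseline creatinine.** Ward transfers: the lowest pre-admission value;
direct ED admissions: the first available value. Candidates ≥ 4 mg/dL are
never eligible; a stay with no eligible candidate is flagged and excluded
upstream. The baseline's measurement time anchors the 7-day clock for the
fold-change criteria (`ratio_anchor="none"` disables the clock).

**Creatinine staging** at each measurement `(t, v)`:

* stage 1 — `v − min over (t−48, t] ≥ 0.3 mg/dL`, or `v ≥ 1.5×baseline`
  on the 7-day clock;
* stage 2 — `v ≥ 2.0×baseline`; stage 3 — `v ≥ 3.0×baseline`;
* `v ≥ 4.0 mg/dL` is stage 3 only with a concurrent stage-1-qualifying
  acute rise (`scr4_requires_acute_rise`, default on). Chronically
  elevated creatinine alone therefore never labels AKI.

Only stage 1 is spelled out in most clinical texts with this design; the
stage-2/3 thresholds and the renal-replacement rule follow the KDIGO 2012
consensus definition.

**Urine staging** uses trailing mean rates `sum of charted volumes in
(t−W, t] / W` at each record time: stage 1 for W = 6 h below 0.5 mL/kg/h,
stage 2 for W = 12 h below 0.5, stage 3 for W = 24 h below 0.3 or zero
output over 12 h. A window is only evaluable when charting covers it:
interior gaps ≤ 2 h, and when charting begins inside the window its first
record must fall within one nominal hour of the window start. Irregular
charting therefore cannot manufacture oliguria; it can only make a window
unevaluable.

**Onset** is the earliest in-ICU firing of any criterion; **stage** is
the maximum attained during the stay (dialysis forces 3); ties at onset
resolve creatinine → urine → dialysis. The same rules restricted to
`t < 0` drive the pre-admission-AKI exclusion (default lookback 7 days).

A deliberately naive oracle (exhaustive loops over all pairs and spans,
in `tests/oracles.py`) implements the same definitions; the vectorized
labeler must agree exactly on 1,000+ randomized stays. Monotonicity is
asserted in its valid form: raising the *latest* creatinine value, or
lowering any urine volume, never lowers the stage or delays the onset.
(The unrestricted form — raising *any* creatinine value — is false for a
relative rise criterion, since raising a past value raises later windows'
minima.)

## Cohort rules

Exclusions are evaluated in a fixed order (age < 20; ESRD on chronic
RRT; AKI before admission; first hemodialysis within 24 h; stay < 30 h,
strictly; repeat admission) and each excluded stay is tallied under its
first matching criterion, so `n_included + Σcounts = n_input` always
balances. A stay of exactly 30.0 h is retained. "Receiving RRT" is read
as chronic dialysis paired with the ESRD flag; incident in-ICU dialysis
instead marks stage-3 AKI.

## Feature windows and extraction

Cases get the 6-h window `(onset−30, onset−24]`: the prediction time is
the window end, 24 h before onset. The clinical-text phrase "window
beginning 24 h before the event" conflicts with a 24-h lead time (such a
window would end only 18 h ahead); we honor the lead time and expose the
alternative anchoring via `window_anchor="start_24h_before"`. Controls
get one random 6-h window with start uniform on `[30, discharge−6]`;
stays under 36 h contribute no control window.

Aggregations: `mean` over in-window records (vitals); `last` takes the
most recent value in a trailing 48-h lookback ending at the prediction
time (labs and creatinine are charted every 6–24 h, so a strictly
in-window "last" would be absent most of the time rather than at the
intended ~10% missingness); trailing 8-/24-h urine totals end at the
window end, and on partially covered spans (windows near admission) the
total is projected from the observed hourly rate, defined whenever ≥ 6 h
are covered — this keeps missingness independent of case/control status,
which matters because an imputed constant is itself a detectable signal;
drug-class flags are 1 iff any administration in the trailing 7 days.
Mean imputation is fitted on derivation-era rows of the fitting site
only; binary features fill 0.

The parsimonious registry contains the eleven features named by the
study's importance analysis (urine totals, diuretic, pulse, creatinine,
systolic/mean BP, temperature, BUN, RAS blocker, respiratory rate)
filled to 21 with age, weight, key labs and drug flags. Weight is
included because the urine features are raw mL totals and weight is their
normalizing covariate (the oliguria criteria are per-kg); without it the
parsimonious model measurably trails the full one. Registries are data:
users can supply their own ordered definitions.

## Models

Defaults (hyperparameters are design choices, recorded in every
artifact): XGBoost 300 trees / depth 4 / lr 0.1; random forest 500
trees; unpenalized logistic regression on standardized inputs; neural
network input → 64 → 32 → 1 (ReLU, sigmoid output, binary cross-entropy)
trained with Adam (lr 1e-2, batch 32, 40 epochs) with L2 weight decay
5e-3 on weight matrices, epoch selection on an internal stratified 20%
validation split, and a 5-member seeded ensemble averaged on the
probability scale. The ensemble and early selection exist because a
small MLP on a few thousand rows otherwise overfits well below its
asymptote; sklearn's MLP served as an independent reference during
development and did not outperform this configuration.

Cross-validation is stratified 5-fold with the imputer refitted inside
each training fold; the Platt calibrator is fitted on the out-of-fold
scores (never on training scores). Platt scaling maximizes the smoothed
Bernoulli likelihood with targets `(N₊+1)/(N₊+2)` and `1/(N₋+2)` by
Newton iteration; the fitted map must be strictly monotone, so calibrated
and raw scores give identical AUROC — asserted to machine precision. The
L1-logistic path is FISTA with warm starts over 30 log-spaced penalties
from the data-derived `λ_max`, scored by cross-validated AUROC with the
one-standard-error rule; the solver is cross-checked against sklearn's
saga at a fixed penalty. The operating threshold for
sensitivity/specificity tables defaults to 0.5 on the calibrated
probability and is configurable; no class reweighting is applied.

## Federated protocol

Per site, derivation-era data are split 80/20 (stratified, seeded);
preprocessing (imputer means and standardization) is site-local, fitted
on the site's training split — mirroring a consortium that ships a
preprocessing recipe rather than pooled statistics, and meaning location
shifts between sites are absorbed locally. Each round: broadcast →
2 local epochs per site (Adam re-initialized each round; a flag persists
moments) → sample-size-weighted FedAvg (uniform averaging behind a
flag) → every site scores the aggregate on its own 20% split. Best
aggregate = argmax of mean validation AUROC over rounds; each site also
tracks its best purely-local model. The server-side code path touches
only weight arrays and scalar scores; a structural test runs the
protocol against a proxy exposing nothing else.

Exact equivalences tested: a K=1 run reproduces sequential local
training bit-near (≤ 1e-10); identical sites leave the aggregate equal
to each local update; analytic MLP gradients (including the L2 term)
match central finite differences to 1e-5 relative.

## Synthetic generator

Each stay draws per-variable latents (standard normal continuous,
Bernoulli drug flags). A shared linear-logistic true model maps nine of
them (age, baseline creatinine, BUN, hemoglobin, lactate, pulse, urine
propensity, diuretic, vasopressor) to the AKI probability; a per-site
intercept is solved by bisection so realized prevalence matches the
configuration while coefficients stay common across sites. Streams are
rendered from the latents: urine and vitals hourly, creatinine every
6–24 h, labs every 12–24 h, small per-record noise, per-stay whole-stream
lab dropout at probability 0.1. Stay durations are lognormal (median
~60 h for controls, ~110 h for AKI stays, truncated at 200/240 h — desk
scale, shorter than real ICU courses). The last quarter of each site's
admissions form the held-out later era.

AKI-positive stays receive a trajectory injection: creatinine inserts a
record at the onset with 1.55×/2.2×/3.4× baseline held thereafter;
urine depresses the hourly rate to 0.42 mL/kg/h for 6 h (stage 1) or
12 h (stage 2), or 6 h at 0.42 then 18 h at 0.22 (stage 3), positioned so
the 6-h rule fires at the onset record. Negative trajectories are bounded
away from every criterion (creatinine noise within ±0.12 mg/dL, urine
floored at 0.75 mL/kg/h), so labeling recovers the injected stage exactly
and the onset within one charting interval — audited over 500+
injections. Stage-3 stays receive a later dialysis event with
probability 0.8.

Site heterogeneity in the default benchmark (5 sites × 4,000 stays,
prevalences 0.30/0.28/0.33/0.31/0.62, era split 0.25) is location-heavy:
±(0.7–1.2) SD offsets with mixed signs on informative latents, mild scale
factors (0.9–1.1), and ±8–12 kg body-weight shifts that confound the raw
urine totals. Location shifts leave within-site separability unchanged
but put a model frozen on the origin's feature distribution off-support
abroad; they are absorbed by the federated sites' local standardization.
Magnitudes were sized so the frozen origin model loses roughly 0.02–0.06
AUROC externally, consistent with the degradation multi-center external
validations report.

**What passing tests show — and don't.** The generator's conditional
outcome model is identical across sites after local standardization, so
federation is pure signal pooling plus shift robustness; real hospitals
can differ in the conditional itself, where FedAvg may transfer less.
Latents are constant within a stay (no physiologic drift, no
pre-onset prodrome outside the injected segments), missingness is
random rather than informative, and charting is regular. Results on this
benchmark validate the *machinery* (labeling, windowing, leakage
discipline, protocol correctness) and the *direction* of the federated
effect, not clinical effect sizes.

**Ground-truth references.** The true linear score gives a Bayes AUROC
on any labeled subset; no trained family may exceed it beyond +0.01
(sampling slack), and the strong learners should come within 0.03 at
n = 10,000 — both asserted. Two generator/extraction defects were caught
by exactly this ceiling during development (truncated urine totals near
admission, and label-dependent missingness of the same), which is the
reason the pipeline treats "no signal beyond the score" as a testable
contract.

## Numerical conventions and degenerate inputs

AUROC is the midrank Mann–Whitney statistic (exact under ties); single-
class inputs raise rather than return NaN. Precision is 0 when nothing
is called positive. Calibration uses 10 equal-width bins, empty bins
omitted. Net benefit is `TP/n − (FP/n)·p_t/(1−p_t)` with `p_t ∈ (0,1)`
strictly. The AUROC-difference test is a paired subject-level bootstrap
(percentile CI, sign-fraction p); bootstrap replicates with a single
class are discarded. Mann–Whitney uses the normal approximation with tie
correction; chi-square is Pearson without continuity correction.
Problem sizes in the shipped tests (4,000 stays/site, 10 benchmark
seeds, n = 10,000 for the ceiling check) are the package's chosen desk
scale.

## Known limitations

No waveform/image data; no multi-window or continuous prediction per
stay; no real networking, secure aggregation or differential privacy in
the FL simulation; tree-family artifacts are re-trained from their
recorded spec rather than deserialized; the synthetic cohorts are not
calibrated to any real population beyond coarse medians.
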