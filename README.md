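# fedaki

A tested, reusable pipeline for predicting acute kidney injury (AKI) in
ICU patients 24 hours before onset, and for studying whether federated
averaging across hospitals improves a single-center model — exercised
end-to-end on a bundled synthetic multi-site ICU data generator, because
real critical-care records are governed by data-use agreements and cannot
ship with code.

## Who this is for

Clinical ML researchers who want a faithful, inspectable implementation
of the standard AKI-prediction study design: KDIGO 2012 labeling from raw
creatinine/urine/dialysis streams, cohort exclusion rules with an
auditable attrition tally, snapshot feature windows with a fixed lead
time, four classifier families with parsimonious L1 feature selection and
Platt calibration, external/temporal validation, and a simulated
FedAvg protocol — all with known ground truth, so every stage can be
verified against an oracle.

## The model

**Labels.** A stay is AKI-positive at the earliest in-ICU time *t* at
which any KDIGO 2012 criterion fires: serum creatinine rise ≥ 0.3 mg/dL
within 48 h; creatinine ≥ 1.5× / 2.0× / 3.0× baseline within 7 days
(stages 1/2/3); urine output < 0.5 mL/kg/h for ≥ 6 h (stage 1) or ≥ 12 h
(stage 2); < 0.3 mL/kg/h for ≥ 24 h or anuria ≥ 12 h (stage 3); any
dialysis is stage 3. Baseline creatinine is the lowest pre-admission
value (ward transfers) or the first available value (direct ED
admissions), excluding values ≥ 4 mg/dL.

**Features.** Cases contribute one 6-h feature window ending 24 h before
onset (the lead time); controls contribute one random 6-h window starting
at ≥ 30 h after admission. Two shipped registries: `FULL_60` (60
features) and `PARSIMONIOUS_21` (21 features: trailing 8-/24-h urine
totals, pulse, creatinine, blood pressures, temperature, BUN,
respiratory rate, key labs, drug-class flags with a 7-day lookback, age,
weight). Missing numerics are mean-imputed on derivation-era data only.

**Models.** Gradient boosting (XGBoost), random forest, unpenalized
logistic regression, and a neural network (input → 64 → 32 → 1, ReLU,
sigmoid, binary cross-entropy, Adam) implemented in numpy with
closed-form gradients. The L1-penalized logistic path (FISTA, 1-SE rule)
and the Platt calibrator `p = 1/(1+exp(a·s+b))` are implemented in-repo.

**Federated averaging.** K = 5 sites, 30 rounds, 2 local epochs per
round, batch 32, Adam at 1e-2. Each round the server broadcasts the
global weights, sites train locally on an 80% split, and the server takes
the sample-size-weighted mean; the best aggregate is the round with the
highest mean validation AUROC across sites. Only weight arrays and scalar
scores cross the site boundary.

**Synthetic data.** A shared linear-logistic true risk model on per-stay
latents drives AKI assignment; injections construct trajectories that the
KDIGO labeler provably recovers (stage exactly, onset within one charting
interval). Sites differ in prevalence, latent location/scale shifts and
body-weight distribution. The true score yields a Bayes AUROC ceiling
that no trained model should beat.

## Worked example

```python
import numpy as np
from fedaki import (SiteConfig, generate_multisite, apply_exclusions,
                    label_aki, extract_cohort, PARSIMONIOUS_21)
from fedaki.modeling import AKIClassifier
from fedaki.evaluation import auroc

data = generate_multisite([SiteConfig("demo", 2000, 0.30)], master_seed=42)
included, tally = apply_exclusions(data["demo"])
events = [label_aki(s) for s in included]
print(f"included {len(included)}/{tally.n_input} stays; "
      f"labeled AKI prevalence {np.mean([e is not None for e in events]):.3f}")

table = extract_cohort(included, events, PARSIMONIOUS_21, seed=0)
deriv = table.subset(table.era_mask["derivation"])
temporal = table.subset(table.era_mask["temporal"])
X = np.where(deriv.missing, np.nan, deriv.X)
model = AKIClassifier("gradient_boosting", seed=0,
                      binary_mask=table.registry.binary_mask).fit(X, deriv.y)
Xt = np.where(temporal.missing, np.nan, temporal.X)
print(f"temporal-era AUROC: {auroc(model.raw_scores(Xt), temporal.y):.3f} "
      f"(n={len(temporal.y)}, cases={temporal.y.sum()})")
```

prints

```
included 1755/2000 stays; labeled AKI prevalence 0.301
temporal-era AUROC: 0.761 (n=408, cases=114)
```

2,000 stays were generated at a configured AKI prevalence of 0.30; 245
were removed by the exclusion rules (age < 20, chronic dialysis,
pre-admission AKI, early hemodialysis, stays < 30 h, repeat admissions),
and the labeled prevalence among the remainder matches the configuration.
A gradient-boosting model fitted on the derivation era discriminates
AKI cases 24 h ahead on the held-out later era with AUROC 0.761 at this
small sample size; at the default benchmark scale (4,000 stays/site) the
temporal AUROCs are around 0.80–0.85 against a Bayes ceiling of ~0.85.

The full study analogue — origin-site development, external validation at
four shifted sites, and the FedAvg comparison — runs from the shell:

```bash
fedaki benchmark --seed 1 --out scratch/bench
```

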