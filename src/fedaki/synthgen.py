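"""Multi-site synthetic ICU cohort generator with known risk structure.

Each stay draws a vector of per-variable latents (standard normal for
continuous variables, Bernoulli for drug-class flags). A shared
linear-logistic true risk model maps a subset of those latents to the
per-stay AKI probability; a per-site intercept is solved so the realized
prevalence matches the site's configuration while the coefficient vector
stays common across sites (so federation has signal to pool). Site
heterogeneity enters as location/scale shifts on the latents and as
differing prevalence.

Event streams are rendered from the latents: urine output hourly, vital
signs hourly, creatinine every 6-24 h (randomized), other labs every
12-24 h, with small per-record measurement noise. AKI-positive stays get
a trajectory injection (`inject_aki`) constructed so the KDIGO labeler
recovers the requested stage exactly and the onset within one charting
interval; AKI-negative trajectories are bounded away from every staging
criterion. Pre-admission creatinine (negative times, up to -168 h)
exercises the baseline rules.

All generation is a pure function of (configs, true model, master seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError
from .types import EventStream, IcuStay

__all__ = [
    "SiteConfig",
    "TrueRiskModel",
    "DEFAULT_TRUE_MODEL",
    "generate_site",
    "generate_multisite",
    "inject_aki",
    "true_scores",
    "bayes_auroc",
    "VITAL_VARS",
    "LAB_VARS",
    "MED_CLASSES",
]

# ---------------------------------------------------------------------------
# variable catalog: (population mean, population SD) on the observed scale
# loosely anchored to adult-ICU summary distributions
VITAL_VARS: Dict[str, Tuple[float, float]] = {
    "pulse": (88.0, 14.0),       # /min
    "sysbp": (122.0, 18.0),      # mmHg
    "dbp": (68.0, 11.0),         # mmHg
    "mbp": (84.0, 12.0),         # mmHg
    "temp": (36.8, 0.5),         # Celsius
    "rr": (18.0, 4.0),           # /min
    "spo2": (96.5, 2.0),         # %
}

LAB_VARS: Dict[str, Tuple[float, float]] = {
    "bun": (22.0, 10.0),         # mg/dL
    "hemoglobin": (10.8, 1.9),   # g/dL
    "platelet": (190.0, 80.0),   # 10^3/uL
    "wbc": (10.5, 3.5),          # 10^3/uL
    "lactate": (16.0, 8.0),      # mg/dL
    "bilirubin": (0.9, 0.6),     # mg/dL
    "pt": (11.5, 1.5),           # s
    "ast": (45.0, 25.0),
    "alt": (32.0, 18.0),
    "albumin": (3.1, 0.5),
    "sodium": (139.0, 4.5),
    "potassium": (4.0, 0.5),
    "chloride": (104.0, 5.0),
    "calcium": (8.6, 0.7),
    "phosphate": (3.4, 0.9),
    "magnesium": (2.0, 0.3),
    "glucose": (145.0, 45.0),
    "bicarbonate": (23.0, 4.0),
    "ph": (7.39, 0.06),
    "pao2": (95.0, 25.0),
    "paco2": (40.0, 7.0),
    "crp": (6.0, 5.0),
    "inr": (1.15, 0.25),
    "ck": (180.0, 120.0),
    "troponin": (0.08, 0.1),
}

#: drug classes with default administration prevalence
MED_CLASSES: Dict[str, float] = {
    "diuretic": 0.35,
    "ras_blocker": 0.20,
    "vasopressor": 0.30,
    "nsaid_cox1": 0.10,
    "nsaid_cox2": 0.04,
    "vancomycin": 0.10,
    "gentamicin": 0.04,
    "colistin": 0.02,
    "amphotericin_b": 0.01,
    "contrast_media": 0.08,
}

#: continuous latents: all vitals and labs plus age, baseline creatinine and
#: the urine-output propensity
CONTINUOUS_LATENTS = ["age", "baseline_scr", "urine_propensity",
                      *VITAL_VARS, *LAB_VARS]

DEFAULT_EXCLUSION_RATES: Dict[str, float] = {
    "age_lt_20": 0.01,
    "esrd_on_rrt": 0.02,
    "aki_before_icu": 0.02,
    "hd_within_24h": 0.01,
    "stay_lt_30h": 0.03,
    "repeat_admission": 0.03,
}


@dataclass(frozen=True)
class TrueRiskModel:
    """Shared linear-logistic ground truth: P(AKI) = sigmoid(b0_site + w.z)."""

    coefficients: Dict[str, float]
    intercept: float = 0.0

    def score(self, latents: Dict[str, float]) -> float:
        return self.intercept + sum(w * latents[k]
                                    for k, w in self.coefficients.items())


#: default ground truth: renal, hemodynamic and exposure drivers of AKI risk
DEFAULT_TRUE_MODEL = TrueRiskModel(coefficients={
    "age": 0.45,
    "baseline_scr": 0.80,
    "bun": 0.60,
    "hemoglobin": -0.40,
    "lactate": 0.50,
    "pulse": 0.40,
    "urine_propensity": -0.70,
    "diuretic": 0.90,
    "vasopressor": 0.70,
})


@dataclass(frozen=True)
class SiteConfig:
    """One simulated hospital."""

    site_id: str
    n_stays: int
    aki_prevalence: float
    #: latent-scale shifts: variable -> (location offset, scale factor)
    covariate_shift: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    era_split: float = 0.25
    missing_prob: float = 0.10  # per-stay, per-lab whole-stream dropout
    exclusion_rates: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXCLUSION_RATES))
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_stays < 1:
            raise ConfigurationError("n_stays must be >= 1")
        if not (0.0 < self.aki_prevalence < 1.0):
            raise ConfigurationError("aki_prevalence must lie in (0, 1)")
        if not (0.0 <= self.era_split < 1.0):
            raise ConfigurationError("era_split must lie in [0, 1)")


# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _solve_intercept(scores: np.ndarray, prevalence: float) -> float:
    """Bisection for b0 with mean(sigmoid(b0 + s)) = prevalence."""
    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _sigmoid(mid + scores).mean() < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _map_baseline_scr(z: np.ndarray) -> np.ndarray:
    return np.clip(0.9 * np.exp(0.25 * z), 0.4, 1.7)


def _map_urine_rate(z: np.ndarray) -> np.ndarray:
    """Baseline urine propensity in mL/kg/h; floor keeps AKI-negative stays
    clear of the oliguria criteria."""
    return np.clip(1.25 + 0.30 * z, 0.80, 2.2)


# oliguria injection levels (mL/kg/h): chosen so the trailing-window rules
# first fire at the requested onset (within one hourly record)
_OLIG_STAGE1 = 0.42
_OLIG_SEVERE = 0.22


def inject_aki(stay: IcuStay, onset: float, stage: int, criterion: str,
               rng: np.random.Generator) -> IcuStay:
    """Overwrite a stay's trajectories so KDIGO labeling fires at ``onset``
    with exactly ``stage``.

    Creatinine injections insert a record at the onset time itself and hold
    subsequent records at the target level (1.55x, 2.2x or 3.4x baseline for
    stages 1-3). Urine injections depress the hourly rate: 6 h at 0.42
    mL/kg/h (stage 1), 12 h at 0.42 (stage 2), or 6 h at 0.42 then 18 h at
    0.22 (stage 3 severe oliguria), positioned so the 6-h rule fires at the
    onset record.
    """
    if stage not in (1, 2, 3):
        raise ValueError("stage must be 1, 2 or 3")
    if criterion not in ("creatinine", "urine"):
        raise ValueError("criterion must be 'creatinine' or 'urine'")
    margin = {"creatinine": 4.0, "urine": {1: 2.0, 2: 8.0, 3: 20.0}[stage]}[criterion]
    if not (30.0 <= onset <= stay.discharge_time - margin):
        raise ValueError(
            f"onset {onset} outside feasible range [30, "
            f"{stay.discharge_time - margin}] for {criterion} stage {stage}")
    out = stay.copy()
    if criterion == "creatinine":
        base = float(stay.truth.get("baseline_scr", stay.creatinine.values.min()))
        factor = {1: 1.55, 2: 2.2, 3: 3.4}[stage]
        target = max(base * factor, base + 0.35)
        t = out.creatinine.times
        v = out.creatinine.values.copy()
        post = t > onset
        v[post] = np.maximum(target + rng.uniform(-0.03, 0.03, int(post.sum())),
                             target - 0.03)
        keep = np.abs(t - onset) > 1e-9
        nt = np.append(t[keep], onset)
        nv = np.append(v[keep], target)
        order = np.argsort(nt, kind="stable")
        out.creatinine = EventStream(nt[order], nv[order], out.creatinine.unit)
    else:
        w = stay.weight
        t = out.urine.times
        v = out.urine.values.copy()
        if t.size == 0:
            raise ValueError("stay has no urine records to depress")
        # snap to the charting grid so the 6-h rule fires at a record time
        onset_r = float(t[np.argmin(np.abs(t - onset))])
        if stage == 1:
            bounds, rates = [(onset_r - 5.0, onset_r)], [_OLIG_STAGE1]
        elif stage == 2:
            bounds, rates = [(onset_r - 5.0, onset_r + 6.0)], [_OLIG_STAGE1]
        else:
            bounds = [(onset_r - 5.0, onset_r), (onset_r + 0.5, onset_r + 18.0)]
            rates = [_OLIG_STAGE1, _OLIG_SEVERE]
        for (lo, hi), rate in zip(bounds, rates):
            m = (t >= lo - 1e-9) & (t <= hi + 1e-9)
            v[m] = w * (rate + rng.uniform(-0.015, 0.015, int(m.sum())))
        out.urine = EventStream(t, v, out.urine.unit)
    out.truth = dict(stay.truth, injected_onset=float(onset),
                     injected_stage=int(stage), injected_criterion=criterion)
    return out


def _feasible_onset(rng: np.random.Generator, stay_end: float, criterion: str,
                    stage: int, anchor: float, ratio_limit: float) -> float:
    margin = {"creatinine": 4.0, "urine": {1: 2.0, 2: 8.0, 3: 20.0}[stage]}[criterion]
    hi = stay_end - margin
    if criterion == "creatinine" and stage >= 2:
        hi = min(hi, anchor + ratio_limit - 8.0)
    lo = 36.0
    if hi <= lo:
        hi = lo + 1.0
    return float(rng.uniform(lo, hi))


def generate_site(config: SiteConfig, true_model: TrueRiskModel,
                  seed_seq: np.random.SeedSequence) -> List[IcuStay]:
    """Generate one site's stays (deterministic in config, model, seed)."""
    rng = np.random.default_rng(seed_seq)
    n = config.n_stays

    # ---- latents (site-shifted standard normals / Bernoulli flags)
    latents: Dict[str, np.ndarray] = {}
    for name in CONTINUOUS_LATENTS:
        z = rng.standard_normal(n)
        loc, scale = config.covariate_shift.get(name, (0.0, 1.0))
        latents[name] = loc + scale * z
    meds: Dict[str, np.ndarray] = {}
    for name, p in MED_CLASSES.items():
        loc, scale = config.covariate_shift.get(name, (0.0, 1.0))
        p_site = float(np.clip(p * scale + loc, 0.005, 0.95))
        meds[name] = rng.random(n) < p_site

    # ---- exclusion specimens (first matching criterion wins)
    u = rng.random(n)
    exclusion = np.full(n, "", dtype=object)
    edge = 0.0
    for crit, rate in config.exclusion_rates.items():
        m = (u >= edge) & (u < edge + rate)
        exclusion[m] = crit
        edge += rate

    eligible = exclusion == ""

    # ---- true score / AKI assignment on eligible stays
    score = np.zeros(n)
    for k, wgt in true_model.coefficients.items():
        x = meds[k].astype(float) if k in meds else latents[k]
        score += wgt * x
    score += true_model.intercept
    b0 = _solve_intercept(score[eligible], config.aki_prevalence)
    p_aki = _sigmoid(b0 + score)
    aki = (rng.random(n) < p_aki) & eligible

    # ---- demographics & durations
    age = np.clip(64.0 + 15.0 * latents["age"], 20.0, 95.0)
    age[exclusion == "age_lt_20"] = rng.uniform(16.0, 19.5,
                                                (exclusion == "age_lt_20").sum())
    wloc, wscale = config.covariate_shift.get("weight", (0.0, 1.0))
    weight = np.clip(65.0 + wloc + 12.0 * wscale * rng.standard_normal(n),
                     40.0, 115.0)
    sex = np.where(rng.random(n) < 0.62, "M", "F")
    source = np.where(rng.random(n) < 0.6, "ED", "ward")

    dur = np.clip(rng.lognormal(np.log(60.0), 0.45, n), 31.0, 200.0)
    dur[aki] = np.clip(rng.lognormal(np.log(110.0), 0.35, int(aki.sum())),
                       72.0, 240.0)
    short = exclusion == "stay_lt_30h"
    dur[short] = rng.uniform(6.0, 29.0, int(short.sum()))

    # ---- era tags: the last round(era_split * n) admissions form the
    # held-out later era
    n_temporal = int(round(config.era_split * n))
    era = np.array(["derivation"] * n, dtype=object)
    if n_temporal:
        era[n - n_temporal:] = "temporal"

    baseline = _map_baseline_scr(latents["baseline_scr"])
    urine_rate = _map_urine_rate(latents["urine_propensity"])

    stage_draw = rng.choice([1, 2, 3], size=n, p=[0.45, 0.25, 0.30])
    crit_draw = np.where(rng.random(n) < 0.6, "creatinine", "urine")
    dialysis_draw = rng.random(n) < 0.8  # among stage-3 stays

    stays: List[IcuStay] = []
    child_seeds = seed_seq.spawn(n)
    for i in range(n):
        srng = np.random.default_rng(child_seeds[i])
        stay = _render_stay(
            config, srng, idx=i, age=float(age[i]), sex=str(sex[i]),
            weight=float(weight[i]), source=str(source[i]),
            duration=float(dur[i]), era=str(era[i]), baseline=float(baseline[i]),
            urine_rate=float(urine_rate[i]),
            latents={k: float(v[i]) for k, v in latents.items()},
            med_flags={k: bool(v[i]) for k, v in meds.items()},
            exclusion=str(exclusion[i]), score=float(score[i]),
            p_aki=float(p_aki[i]),
        )
        if aki[i]:
            stage = int(stage_draw[i])
            crit = str(crit_draw[i])
            anchor = stay.truth["baseline_anchor"]
            onset = _feasible_onset(srng, stay.discharge_time, crit, stage,
                                    anchor, 168.0)
            if crit == "urine":
                # align with hourly charting, staying inside the margins
                margin = {1: 2.0, 2: 8.0, 3: 20.0}[stage]
                onset = float(np.clip(round(onset), 36.0,
                                      np.floor(stay.discharge_time - margin)))
            stay = inject_aki(stay, onset, stage, crit, srng)
            if stage == 3 and dialysis_draw[i]:
                t_hd = min(onset + float(srng.uniform(4.0, 24.0)),
                           stay.discharge_time - 1.0)
                if t_hd > onset:
                    stay.dialysis_times.append(float(t_hd))
        stays.append(stay)
    return stays


def _render_stay(config: SiteConfig, rng: np.random.Generator, idx: int,
                 age: float, sex: str, weight: float, source: str,
                 duration: float, era: str, baseline: float, urine_rate: float,
                 latents: Dict[str, float], med_flags: Dict[str, bool],
                 exclusion: str, score: float, p_aki: float) -> IcuStay:
    """Render one AKI-negative stay's event streams from its latents."""
    esrd = prior_rrt = False
    first_adm = True
    dialysis: List[float] = []
    if exclusion == "esrd_on_rrt":
        esrd = prior_rrt = True
    elif exclusion == "repeat_admission":
        first_adm = False
    elif exclusion == "hd_within_24h":
        dialysis.append(float(rng.uniform(2.0, 20.0)))

    # creatinine: pre-admission record (ward) + in-ICU every 6-24 h
    pre_t: List[float] = []
    pre_v: List[float] = []
    if source == "ward":
        n_pre = int(rng.integers(2, 5))
        t_pre = -np.sort(rng.uniform(6.0, 120.0, n_pre))[::-1]  # ascending
        v_pre = baseline + rng.uniform(0.02, 0.15, n_pre)
        v_pre[-1] = baseline  # lowest value closest to admission
        pre_t, pre_v = list(t_pre), list(v_pre)
        anchor = float(t_pre[-1])
    icu_t = [float(rng.uniform(0.2, 2.0))]
    while icu_t[-1] < duration - 6.0:
        icu_t.append(icu_t[-1] + float(rng.uniform(6.0, 24.0)))
    icu_t = [t for t in icu_t if t <= duration]
    icu_v = baseline + rng.uniform(-0.08, 0.12, len(icu_t))
    if source == "ED":
        icu_v[0] = baseline  # first available value is the baseline
        anchor = float(icu_t[0])
    if exclusion == "aki_before_icu":
        # acute pre-admission rise that satisfies the 0.3 mg/dL / 48 h rule
        pre_t = [-70.0, -30.0]
        pre_v = [baseline, baseline + 0.5]
        anchor = -70.0
    creat = EventStream(np.array(pre_t + icu_t),
                        np.clip(np.array(pre_v + list(icu_v)), 0.3, None),
                        "mg/dL")

    n_hours = int(duration)
    hours = np.arange(1.0, n_hours + 1.0)

    urine_v = weight * np.maximum(
        urine_rate + rng.normal(0.0, 0.08, n_hours), 0.75)
    urine = EventStream(hours, urine_v, "mL")

    vitals = {}
    for name, (mu, sd) in VITAL_VARS.items():
        level = mu + sd * latents[name]
        vitals[name] = EventStream(
            hours, level + 0.15 * sd * rng.standard_normal(n_hours), "")

    labs = {}
    for name, (mu, sd) in LAB_VARS.items():
        if rng.random() < config.missing_prob:
            continue  # whole-stream dropout exercises imputation
        t0 = float(rng.uniform(1.0, 12.0))
        step = float(rng.uniform(12.0, 24.0))
        t_lab = np.arange(t0, duration, step)
        level = mu + sd * latents[name]
        vals = level + 0.10 * sd * rng.standard_normal(t_lab.size)
        floor = 0.05 * mu if mu > 0 else None
        if floor is not None:
            vals = np.maximum(vals, floor)
        labs[name] = EventStream(t_lab, vals, "")

    medications = []
    for name, flag in med_flags.items():
        if flag:
            t_med = float(rng.uniform(0.0, 6.0))
            while t_med < duration:
                medications.append((name, t_med))
                t_med += 24.0

    return IcuStay(
        stay_id=f"{config.site_id}-{idx:05d}", site_id=config.site_id,
        age=age, sex=sex, weight=weight, admission_source=source,
        discharge_time=duration, era=era, esrd=esrd, prior_rrt=prior_rrt,
        first_icu_admission=first_adm, creatinine=creat, urine=urine,
        vitals=vitals, labs=labs, medications=medications,
        dialysis_times=dialysis,
        truth={"score": score, "p_aki": p_aki, "baseline_scr": baseline,
               "baseline_anchor": anchor, "urine_rate": urine_rate,
               "latents": latents, "med_flags": med_flags,
               "exclusion": exclusion},
    )


def generate_multisite(configs: Sequence[SiteConfig],
                       true_model: TrueRiskModel = DEFAULT_TRUE_MODEL,
                       master_seed: int = 0) -> Dict[str, List[IcuStay]]:
    """Generate all sites; returns an ordered mapping site_id -> stays."""
    if not configs:
        raise ConfigurationError("at least one SiteConfig is required")
    ids = [c.site_id for c in configs]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("site_ids must be unique")
    out: Dict[str, List[IcuStay]] = {}
    for k, cfg in enumerate(configs):
        entropy = cfg.seed if cfg.seed is not None else k
        ss = np.random.SeedSequence([int(master_seed), int(entropy)])
        out[cfg.site_id] = generate_site(cfg, true_model, ss)
    return out


def true_scores(stays: Sequence[IcuStay],
                true_model: TrueRiskModel = DEFAULT_TRUE_MODEL) -> np.ndarray:
    """Ground-truth linear risk scores (for Bayes-bound references)."""
    out = np.empty(len(stays))
    for i, s in enumerate(stays):
        lat = dict(s.truth["latents"])
        lat.update({k: float(v) for k, v in s.truth["med_flags"].items()})
        out[i] = true_model.score(lat)
    return out


def bayes_auroc(stays: Sequence[IcuStay], labels: np.ndarray,
                true_model: TrueRiskModel = DEFAULT_TRUE_MODEL) -> float:
    """AUROC of the true risk score against realized labels: the ceiling no
    trained model can beat beyond sampling noise."""
    from .evaluation import auroc

    return auroc(true_scores(stays, true_model), np.asarray(labels))
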