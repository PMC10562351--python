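"""Prediction windows, feature registries, extraction and mean imputation.

One feature vector per included stay: AKI cases get the 6-h window ending
24 h before onset (prediction time = window end, giving the 24-h lead
time); controls get a random 6-h window starting at or after 30 h. The
alternative anchoring (window *starting* 24 h before onset) is available
via ``window_anchor="start_24h_before"``.

A registry is an ordered list of feature definitions (name, source
stream, aggregation, kind). Two defaults ship: FULL_60 and
PARSIMONIOUS_21; both are data, not code, and can be overridden.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ImputationError, RegistryError
from .synthgen import LAB_VARS, VITAL_VARS
from .types import AKIEvent, EventStream, IcuStay

__all__ = [
    "Window", "FeatureDef", "FeatureRegistry", "FULL_60", "PARSIMONIOUS_21",
    "case_window", "control_window", "extract", "extract_cohort",
    "MeanImputer",
]

WINDOW_H = 6.0
LEAD_TIME_H = 24.0
MED_LOOKBACK_H = 168.0
CONTROL_MIN_START_H = 30.0
#: "last" takes the most recent value known at the prediction time, looking
#: back at most this far (labs are charted every 12-24 h, so a within-window
#: "last" would be absent most of the time rather than the intended ~10%)
LAST_LOOKBACK_H = 48.0


@dataclass(frozen=True)
class Window:
    start: float
    end: float
    role: str  # "case" | "control"

    def __post_init__(self) -> None:
        if abs((self.end - self.start) - WINDOW_H) > 1e-9:
            raise ValueError("feature windows are exactly 6 h long")


@dataclass(frozen=True)
class FeatureDef:
    name: str
    source: str  # stream name, "urine", "creatinine", demographic, or med class(es)
    aggregation: str  # mean | last | sum_8h | sum_24h | binary_7d | identity
    kind: str = "numeric"  # numeric | binary


class FeatureRegistry:
    """Ordered, named feature definitions with a content hash."""

    def __init__(self, name: str, defs: Sequence[FeatureDef]):
        names = [d.name for d in defs]
        if len(set(names)) != len(names):
            raise RegistryError("feature names must be unique")
        self.name = name
        self.defs = list(defs)

    def __len__(self) -> int:
        return len(self.defs)

    @property
    def feature_names(self) -> List[str]:
        return [d.name for d in self.defs]

    @property
    def binary_mask(self) -> np.ndarray:
        return np.array([d.kind == "binary" for d in self.defs])

    @property
    def hash(self) -> str:
        blob = json.dumps([(d.name, d.source, d.aggregation, d.kind)
                           for d in self.defs]).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _demo(name: str) -> FeatureDef:
    return FeatureDef(name, name, "identity")


def _meds(name: str, classes: str) -> FeatureDef:
    return FeatureDef(name, classes, "binary_7d", "binary")


_PARSIMONIOUS_DEFS = [
    FeatureDef("urine_8h", "urine", "sum_8h"),
    FeatureDef("urine_24h", "urine", "sum_24h"),
    _meds("diuretic", "diuretic"),
    FeatureDef("pulse", "pulse", "mean"),
    FeatureDef("creatinine", "creatinine", "last"),
    FeatureDef("sysbp", "sysbp", "mean"),
    FeatureDef("mbp", "mbp", "mean"),
    FeatureDef("temp", "temp", "mean"),
    FeatureDef("bun", "bun", "last"),
    _meds("ras_blocker", "ras_blocker"),
    FeatureDef("rr", "rr", "mean"),
    _demo("age"),
    FeatureDef("hemoglobin", "hemoglobin", "last"),
    FeatureDef("platelet", "platelet", "last"),
    FeatureDef("wbc", "wbc", "last"),
    FeatureDef("lactate", "lactate", "last"),
    FeatureDef("bilirubin", "bilirubin", "last"),
    FeatureDef("pt", "pt", "last"),
    _meds("vasopressor", "vasopressor"),
    _meds("nsaid", "nsaid_cox1|nsaid_cox2"),
    # body weight rather than a further low-prevalence drug class: the
    # urine-volume features are charted in raw mL, so weight is the
    # normalizing covariate any data-driven selection retains
    _demo("weight"),
]

PARSIMONIOUS_21 = FeatureRegistry("parsimonious_21", _PARSIMONIOUS_DEFS)

_FULL_DEFS = [
    _demo("age"), _demo("weight"), _demo("sex_male"),
    *[FeatureDef(v, v, "mean") for v in VITAL_VARS],
    *[FeatureDef(f"{v}_last", v, "last") for v in VITAL_VARS],
    FeatureDef("urine_8h", "urine", "sum_8h"),
    FeatureDef("urine_24h", "urine", "sum_24h"),
    FeatureDef("creatinine", "creatinine", "last"),
    FeatureDef("creatinine_mean", "creatinine", "mean"),
    *[FeatureDef(l, l, "last") for l in LAB_VARS],
    *[FeatureDef(f"{l}_mean", l, "mean")
      for l in ("bun", "hemoglobin", "lactate", "wbc")],
    *[_meds(m, m) for m in ("diuretic", "ras_blocker", "vasopressor",
                            "nsaid_cox1", "nsaid_cox2", "vancomycin",
                            "gentamicin", "colistin", "amphotericin_b",
                            "contrast_media")],
]

FULL_60 = FeatureRegistry("full_60", _FULL_DEFS)
assert len(FULL_60) == 60, len(FULL_60)

REGISTRIES = {"full_60": FULL_60, "parsimonious_21": PARSIMONIOUS_21}


# ---------------------------------------------------------------------------
# windows


def case_window(onset: float, anchor: str = "end_24h_before") -> Optional[Window]:
    """6-h case window with 24-h lead time; None when onset is too early."""
    if anchor == "end_24h_before":
        start = onset - LEAD_TIME_H - WINDOW_H
    elif anchor == "start_24h_before":
        start = onset - LEAD_TIME_H
    else:
        raise ValueError(f"unknown window anchor {anchor!r}")
    if start < 0:
        return None
    return Window(start, start + WINDOW_H, "case")


def control_window(stay: IcuStay, rng: np.random.Generator) -> Optional[Window]:
    """Random 6-h window starting uniformly in [30, discharge - 6]."""
    latest = stay.discharge_time - WINDOW_H
    if latest < CONTROL_MIN_START_H:
        return None
    start = float(rng.uniform(CONTROL_MIN_START_H, latest))
    return Window(start, start + WINDOW_H, "control")


# ---------------------------------------------------------------------------
# extraction


def _stream(stay: IcuStay, source: str) -> Optional[EventStream]:
    if source == "creatinine":
        return stay.creatinine
    if source == "urine":
        return stay.urine
    if source in stay.vitals:
        return stay.vitals[source]
    if source in stay.labs:
        return stay.labs.get(source)
    from .synthgen import LAB_VARS as _L, VITAL_VARS as _V
    if source in _L or source in _V:
        return None  # known stream, absent for this stay -> missing
    raise RegistryError(f"unknown source stream {source!r}")


def extract(stay: IcuStay, window: Window, registry: FeatureRegistry,
            label: Optional[int] = None) -> Tuple[np.ndarray, np.ndarray]:
    """(values, missing_mask) for one stay and window, in registry order.

    Numeric aggregations use records in (start, end]; trailing urine sums
    end at the window end; medication flags look back 7 days from the
    window end. Absent records set the missing mask (binary features are
    never missing: no record means 0).
    """
    values = np.full(len(registry), np.nan)
    missing = np.zeros(len(registry), dtype=bool)
    end = window.end
    for j, d in enumerate(registry.defs):
        if d.aggregation == "identity":
            if d.source == "age":
                values[j] = stay.age
            elif d.source == "weight":
                values[j] = stay.weight
            elif d.source == "sex_male":
                values[j] = 1.0 if stay.sex == "M" else 0.0
            else:
                raise RegistryError(f"unknown demographic {d.source!r}")
            continue
        if d.aggregation == "binary_7d":
            classes = set(d.source.split("|"))
            values[j] = float(any(cls in classes
                                  and end - MED_LOOKBACK_H < t <= end
                                  for cls, t in stay.medications))
            continue
        stream = _stream(stay, d.source)
        if d.aggregation in ("sum_8h", "sum_24h"):
            span = 8.0 if d.aggregation == "sum_8h" else 24.0
            sub = stream.between(end - span, end) if stream else None
            if sub is None or len(sub) == 0:
                missing[j] = True
                continue
            # hours the charting actually covers inside the span; totals on
            # partially covered spans (windows near admission) are projected
            # from the observed hourly rate so the feature is defined
            # whenever at least 6 h are covered
            cover_start = max(end - span, float(stream.times.min()) - 1.0)
            hours = end - cover_start
            if hours < 6.0 - 1e-9:
                missing[j] = True
            else:
                values[j] = float(sub.values.sum()) * span / hours
            continue
        if d.aggregation == "mean":
            sub = stream.between(window.start, end) if stream else None
            if sub is None or len(sub) == 0:
                missing[j] = True
            else:
                values[j] = float(sub.values.mean())
        elif d.aggregation == "last":
            sub = stream.between(end - LAST_LOOKBACK_H, end) if stream else None
            if sub is None or len(sub) == 0:
                missing[j] = True
            else:
                values[j] = float(sub.values[-1])
        else:
            raise RegistryError(f"unknown aggregation {d.aggregation!r}")
    return values, missing


def extract_cohort(stays: Sequence[IcuStay],
                   events: Sequence[Optional[AKIEvent]],
                   registry: FeatureRegistry,
                   grouping: str = "all_stage",
                   window_anchor: str = "end_24h_before",
                   seed: int = 0) -> "FeatureTable":
    """One feature vector per stay: case windows for stays in the chosen
    severity grouping, random control windows otherwise. Stays without a
    feasible window are skipped (reason recorded)."""
    from .types import in_group

    rng = np.random.default_rng(seed)
    rows, masks, labels, meta, skipped = [], [], [], [], []
    for stay, event in zip(stays, events):
        is_case = in_group(event, grouping,
                           had_dialysis=(event is not None
                                         and (event.criterion == "dialysis"
                                              or bool(stay.dialysis_times))))
        if is_case:
            win = case_window(event.onset, window_anchor)
            if win is None:
                skipped.append((stay.stay_id, "onset_too_early"))
                continue
        else:
            win = control_window(stay, rng)
            if win is None:
                skipped.append((stay.stay_id, "stay_too_short"))
                continue
        v, m = extract(stay, win, registry)
        rows.append(v)
        masks.append(m)
        labels.append(int(is_case))
        meta.append((stay.stay_id, stay.site_id, stay.era, win.start, win.end,
                     win.role))
    X = np.vstack(rows) if rows else np.empty((0, len(registry)))
    return FeatureTable(
        X=X, missing=np.vstack(masks) if masks else np.empty((0, len(registry)), bool),
        y=np.asarray(labels, dtype=int), registry=registry,
        stay_ids=[m[0] for m in meta], site_ids=[m[1] for m in meta],
        eras=[m[2] for m in meta], windows=[(m[3], m[4], m[5]) for m in meta],
        skipped=skipped,
    )


@dataclass
class FeatureTable:
    """Fixed-order feature matrix with metadata for one cohort."""

    X: np.ndarray
    missing: np.ndarray
    y: np.ndarray
    registry: FeatureRegistry
    stay_ids: List[str]
    site_ids: List[str]
    eras: List[str]
    windows: List[Tuple[float, float, str]]
    skipped: List[Tuple[str, str]]
    #: generator ground-truth risk scores aligned with rows (synthetic data)
    truth_scores: Optional[np.ndarray] = None

    @property
    def era_mask(self) -> Dict[str, np.ndarray]:
        eras = np.asarray(self.eras)
        return {"derivation": eras == "derivation", "temporal": eras == "temporal"}

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        idx = np.flatnonzero(mask)
        return FeatureTable(
            X=self.X[idx], missing=self.missing[idx], y=self.y[idx],
            registry=self.registry,
            stay_ids=[self.stay_ids[i] for i in idx],
            site_ids=[self.site_ids[i] for i in idx],
            eras=[self.eras[i] for i in idx],
            windows=[self.windows[i] for i in idx], skipped=[],
            truth_scores=(None if self.truth_scores is None
                          else self.truth_scores[idx]))


class MeanImputer(BaseEstimator, TransformerMixin):
    """Column-mean imputation for numeric features; binary features fill 0.

    Fit only on derivation-era rows of the fitting site(s) to avoid
    temporal leakage; the caller controls what goes into ``fit``.
    """

    def __init__(self, binary_mask: Optional[np.ndarray] = None):
        self.binary_mask = binary_mask

    def fit(self, X: np.ndarray, y=None) -> "MeanImputer":
        X = np.asarray(X, dtype=float)
        mask = (np.zeros(X.shape[1], bool) if self.binary_mask is None
                else np.asarray(self.binary_mask, bool))
        means = np.full(X.shape[1], np.nan)
        with np.errstate(invalid="ignore"):
            obs = ~np.isnan(X)
            for j in range(X.shape[1]):
                if mask[j]:
                    means[j] = 0.0
                elif obs[:, j].any():
                    means[j] = X[obs[:, j], j].mean()
                else:
                    raise ImputationError(
                        f"feature column {j} observed nowhere in the fit set")
        self.means_ = means
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float).copy()
        if X.shape[1] != self.means_.size:
            raise ImputationError("column count mismatch with fitted means")
        nan = np.isnan(X)
        X[nan] = np.broadcast_to(self.means_, X.shape)[nan]
        return X
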