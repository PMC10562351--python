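"""Discrimination, calibration, clinical-utility and inference metrics.

AUROC is computed as the Mann-Whitney pair statistic
(wins + 0.5 * ties) / (n_pos * n_neg) via midranks, so it agrees exactly
with brute-force pair counting. Net benefit follows the decision-curve
convention NB(p_t) = TP/n - (FP/n) * p_t / (1 - p_t).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import RegistryError, UndefinedMetricError

__all__ = [
    "auroc",
    "threshold_metrics",
    "calibration_curve",
    "net_benefit",
    "perm_importance",
    "compare_auroc",
    "cohort_summary",
    "EvalReport",
    "evaluate",
]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if labels.min() < 0 or labels.max() > 1:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise UndefinedMetricError("both classes must be present")
    return labels


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUROC, exact under ties."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(np.asarray(labels))
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)  # midranks handle ties as 0.5 wins
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def threshold_metrics(scores: Sequence[float], labels: Sequence[int],
                      threshold: float) -> Tuple[float, float, float, float]:
    """(sensitivity, specificity, precision, accuracy) with positive calls
    at score >= threshold; precision is 0 when nothing is called positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    acc = (tp + tn) / labels.size
    return sens, spec, prec, acc


def calibration_curve(probs: Sequence[float], labels: Sequence[int],
                      n_bins: int = 10) -> List[Tuple[float, float, int]]:
    """Equal-width reliability bins on [0, 1]: (mean predicted, observed
    fraction, count) per non-empty bin."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    idx = np.minimum((probs * n_bins).astype(int), n_bins - 1)
    out = []
    for b in range(n_bins):
        m = idx == b
        if m.any():
            out.append((float(probs[m].mean()), float(labels[m].mean()),
                        int(m.sum())))
    return out


def net_benefit(probs: Sequence[float], labels: Sequence[int],
                thresholds: Sequence[float]) -> pd.DataFrame:
    """Decision curve: net benefit of the classifier plus treat-all and
    treat-none references at each threshold probability."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    n = labels.size
    prev = labels.mean()
    rows = []
    for pt in thresholds:
        if not (0.0 < pt < 1.0):
            continue  # p_t = 0 or 1 is degenerate and excluded
        pred = probs >= pt
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        odds = pt / (1.0 - pt)
        rows.append({
            "threshold": pt,
            "net_benefit": tp / n - (fp / n) * odds,
            "treat_all": prev - (1.0 - prev) * odds,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


def perm_importance(model, X: np.ndarray, y: np.ndarray,
                    feature_names: Sequence[str], n_repeats: int = 5,
                    seed: int = 0) -> pd.DataFrame:
    """Mean AUROC drop per feature under within-column permutation."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(feature_names):
        raise RegistryError("feature_names length must match X columns")
    rng = np.random.default_rng(seed)
    base = auroc(model.predict_proba(X)[:, 1], y)
    drops = np.zeros((len(feature_names), n_repeats))
    for j in range(X.shape[1]):
        col = X[:, j].copy()
        if np.all(col == col[0]):
            continue  # constant feature: drop is exactly 0
        for r in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(col)
            drops[j, r] = base - auroc(model.predict_proba(Xp)[:, 1], y)
    df = pd.DataFrame({"feature": list(feature_names),
                       "mean_drop": drops.mean(axis=1),
                       "n_repeats": n_repeats})
    return df.sort_values("mean_drop", ascending=False).reset_index(drop=True)


def compare_auroc(scores_a: Sequence[float], scores_b: Sequence[float],
                  labels: Sequence[int], n_boot: int = 2000,
                  seed: int = 0) -> Dict[str, float]:
    """Paired-bootstrap inference on delta AUROC = AUROC(b) - AUROC(a).

    Resamples subjects with replacement; returns the point estimate, a
    percentile 95% CI and a two-sided sign-fraction p-value.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = _check_binary(np.asarray(labels))
    if a.size != b.size or a.size != y.size:
        raise ValueError("score vectors and labels must align")
    delta = auroc(b, y) - auroc(a, y)
    rng = np.random.default_rng(seed)
    n = y.size
    boots = np.empty(n_boot)
    k = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if y[idx].min() == y[idx].max():
            continue
        boots[k] = auroc(b[idx], y[idx]) - auroc(a[idx], y[idx])
        k += 1
    boots = boots[:k]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    p = 2.0 * min((boots <= 0).mean(), (boots >= 0).mean())
    return {"delta": float(delta), "ci_low": float(lo), "ci_high": float(hi),
            "p_value": float(min(p, 1.0)), "n_boot": int(k)}


def cohort_summary(group_a: pd.DataFrame, group_b: pd.DataFrame,
                   categorical: Sequence[str] = ()) -> pd.DataFrame:
    """Median (IQR) / n (%) comparison table with Mann-Whitney U and
    chi-square tests; significance flagged at p < 0.05."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for col in group_a.columns:
        if col not in group_b.columns:
            continue
        a = group_a[col].dropna()
        b = group_b[col].dropna()
        if col in categorical or a.dtype == bool or a.dtype == object:
            tab = pd.crosstab(
                np.concatenate([np.zeros(len(a)), np.ones(len(b))]),
                np.concatenate([np.asarray(a), np.asarray(b)]))
            if tab.shape[1] < 2:
                stat_p = 1.0
            else:
                _, stat_p, _, _ = stats.chi2_contingency(tab.values,
                                                         correction=False)
            pos_a = np.asarray(a).astype(bool)
            pos_b = np.asarray(b).astype(bool)
            rows.append({
                "variable": col, "type": "categorical",
                "group_a": f"{pos_a.sum()} ({100 * pos_a.mean():.1f}%)",
                "group_b": f"{pos_b.sum()} ({100 * pos_b.mean():.1f}%)",
                "p_value": float(stat_p),
            })
        else:
            if a.nunique() == 1 and b.nunique() == 1 and a.iloc[0] == b.iloc[0]:
                stat_p = 1.0
            else:
                _, stat_p = stats.mannwhitneyu(a, b, alternative="two-sided")
            qa = np.percentile(a, [25, 50, 75])
            qb = np.percentile(b, [25, 50, 75])
            rows.append({
                "variable": col, "type": "continuous",
                "group_a": f"{qa[1]:.1f} ({qa[0]:.1f}-{qa[2]:.1f})",
                "group_b": f"{qb[1]:.1f} ({qb[0]:.1f}-{qb[2]:.1f})",
                "p_value": float(stat_p),
            })
    df = pd.DataFrame(rows)
    df["significant"] = df["p_value"] < 0.05
    return df


@dataclass
class EvalReport:
    """One model-on-one-cohort evaluation."""

    auroc: float
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    threshold: float
    n: int
    n_pos: int
    calibration: List[Tuple[float, float, int]] = field(default_factory=list)
    decision_curve: Optional[pd.DataFrame] = None

    def to_dict(self) -> Dict[str, float]:
        return {
            "auroc": self.auroc, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision,
            "accuracy": self.accuracy, "threshold": self.threshold,
            "n": self.n, "n_pos": self.n_pos,
        }


def evaluate(probs: Sequence[float], labels: Sequence[int],
             threshold: float = 0.5, n_bins: int = 10,
             dca_grid: Optional[Sequence[float]] = None) -> EvalReport:
    """Full evaluation bundle at one operating threshold."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    sens, spec, prec, acc = threshold_metrics(probs, labels, threshold)
    if dca_grid is None:
        dca_grid = np.arange(0.05, 0.95, 0.05)
    return EvalReport(
        auroc=auroc(probs, labels), sensitivity=sens, specificity=spec,
        precision=prec, accuracy=acc, threshold=threshold,
        n=int(labels.size), n_pos=int(labels.sum()),
        calibration=calibration_curve(np.clip(probs, 0, 1), labels, n_bins),
        decision_curve=net_benefit(probs, labels, dca_grid),
    )
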