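"""Report figures: ROC, reliability and decision curves as SVG/PNG."""

from __future__ import annotations

import os
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .evaluation import calibration_curve, net_benefit  # noqa: E402

__all__ = ["plot_model_evaluation"]


def plot_model_evaluation(probs: Sequence[float], labels: Sequence[int],
                          out_dir: str, prefix: str = "model",
                          fmt: str = "svg") -> list:
    """Write ROC, calibration and decision-curve panels for one model."""
    from sklearn.metrics import roc_curve

    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    os.makedirs(out_dir, exist_ok=True)
    paths = []

    fpr, tpr, _ = roc_curve(labels, probs)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, lw=1.5)
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    ax.set_title("ROC")
    paths.append(_save(fig, out_dir, f"{prefix}_roc", fmt))

    bins = calibration_curve(np.clip(probs, 0, 1), labels)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot([b[0] for b in bins], [b[1] for b in bins], "o-", lw=1.2)
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("Predicted probability")
    ax.set_ylabel("Observed fraction")
    ax.set_title("Calibration")
    paths.append(_save(fig, out_dir, f"{prefix}_calibration", fmt))

    dca = net_benefit(probs, labels, np.arange(0.02, 0.9, 0.02))
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.plot(dca["threshold"], dca["net_benefit"], label="model", lw=1.5)
    ax.plot(dca["threshold"], dca["treat_all"], label="treat all", lw=1.0)
    ax.plot(dca["threshold"], dca["treat_none"], label="treat none", lw=1.0)
    ax.set_ylim(bottom=-0.05)
    ax.set_xlabel("Threshold probability")
    ax.set_ylabel("Net benefit")
    ax.legend(frameon=False)
    ax.set_title("Decision curve")
    paths.append(_save(fig, out_dir, f"{prefix}_decision_curve", fmt))
    return paths


def _save(fig, out_dir: str, name: str, fmt: str) -> str:
    path = os.path.join(out_dir, f"{name}.{fmt}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
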