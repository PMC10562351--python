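"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain loops over pairs and spans, sharing
nothing with the package's vectorized code paths.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np


def brute_auroc(scores, labels) -> float:
    """Pair-counting AUROC: (wins + 0.5 * ties) / (n_pos * n_neg)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((wins + 0.5 * ties) / (pos.size * neg.size))


def brute_stage_creatinine(times, values, baseline_value, anchor_time,
                           ratio_window_h=168.0, rise_window_h=48.0,
                           rise_threshold=0.3, scr4_requires_acute_rise=True
                           ) -> List[Tuple[float, int]]:
    out = []
    n = len(times)
    for j in range(n):
        t, v = times[j], values[j]
        window_min = min(values[i] for i in range(n)
                         if t - rise_window_h < times[i] <= t)
        rise = (v - window_min) >= rise_threshold
        on_clock = (t - anchor_time) <= ratio_window_h
        ratio = v / baseline_value
        s1 = rise or (ratio >= 1.5 and on_clock)
        s2 = ratio >= 2.0 and on_clock
        s3 = (ratio >= 3.0 and on_clock) or (
            v >= 4.0 and (s1 or not scr4_requires_acute_rise))
        stage = 3 if s3 else 2 if s2 else 1 if s1 else 0
        if stage:
            out.append((float(t), stage))
    return out


def _brute_window(times, volumes, j, window_h, gap_h=2.0):
    """(evaluable, mean rate) for the trailing window ending at index j."""
    t_end = times[j]
    start = t_end - window_h
    idx = [i for i in range(len(times)) if start < times[i] <= t_end]
    if not idx:
        return False, None
    entering = gap_h if idx[0] > 0 else 1.0
    if times[idx[0]] - start > entering:
        return False, None
    for a, b in zip(idx[:-1], idx[1:]):
        if times[b] - times[a] > gap_h:
            return False, None
    return True, sum(volumes[i] for i in idx) / window_h


def brute_stage_urine(times, volumes, weight,
                      gap_h=2.0) -> List[Tuple[float, int]]:
    out = []
    for j in range(len(times)):
        stage = 0
        ok6, r6 = _brute_window(times, volumes, j, 6.0, gap_h)
        ok12, r12 = _brute_window(times, volumes, j, 12.0, gap_h)
        ok24, r24 = _brute_window(times, volumes, j, 24.0, gap_h)
        if ok6 and r6 / weight < 0.5:
            stage = 1
        if ok12 and r12 / weight < 0.5:
            stage = 2
        if (ok24 and r24 / weight < 0.3) or (ok12 and r12 == 0.0):
            stage = 3
        if stage:
            out.append((float(times[j]), stage))
    return out


def brute_label(stay, baseline) -> Optional[Tuple[float, int, str]]:
    """(onset, stage, criterion) by exhaustive scanning, or None."""
    firings = []
    ct = list(stay.creatinine.times)
    cv = list(stay.creatinine.values)
    for t, s in brute_stage_creatinine(ct, cv, baseline.value,
                                       baseline.anchor_time):
        if 0 <= t <= stay.discharge_time:
            firings.append((t, s, "creatinine"))
    for t, s in brute_stage_urine(list(stay.urine.times),
                                  list(stay.urine.values), stay.weight):
        if 0 <= t <= stay.discharge_time:
            firings.append((t, s, "urine"))
    for t in stay.dialysis_times:
        if 0 <= t <= stay.discharge_time:
            firings.append((float(t), 3, "dialysis"))
    if not firings:
        return None
    prio = {"creatinine": 0, "urine": 1, "dialysis": 2}
    onset, _, crit = min(firings, key=lambda f: (f[0], prio[f[2]]))
    stage = max(f[1] for f in firings)
    return onset, stage, crit


def brute_mannwhitney_u(a, b) -> float:
    """U statistic of sample a by exhaustive pair comparison."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else 0.5 if x == y else 0.0
    return u


def random_short_stay(rng: np.random.Generator):
    """A randomized small stay exercising every staging rule combination."""
    from fedaki.types import EventStream, IcuStay

    source = "ward" if rng.random() < 0.5 else "ED"
    discharge = float(rng.uniform(40.0, 120.0))
    n_creat = int(rng.integers(4, 14))
    lo = -72.0 if source == "ward" else 0.2
    ct = np.sort(rng.uniform(lo, discharge, n_creat))
    if source == "ward" and not (ct < 0).any():
        ct[0] = rng.uniform(-72.0, -1.0)
        ct = np.sort(ct)
    cv = rng.uniform(0.4, 4.6, n_creat)
    if source == "ward" and not ((ct < 0) & (cv < 4.0)).any():
        cv[np.flatnonzero(ct < 0)[0]] = rng.uniform(0.5, 3.5)
    if source == "ED" and not (cv < 4.0).any():
        cv[0] = rng.uniform(0.5, 3.5)
    steps = rng.choice([1.0, 1.0, 1.0, 1.0, 2.0, 3.0],
                       size=int(rng.integers(12, 60)))
    ut = np.cumsum(steps) + rng.uniform(0.0, 2.0)
    ut = ut[ut < discharge]
    weight = float(rng.uniform(45.0, 100.0))
    uv = rng.uniform(0.0, 1.6, ut.size) * weight
    uv[rng.random(ut.size) < 0.15] = 0.0
    dial = [float(rng.uniform(0, discharge))] if rng.random() < 0.1 else []
    return IcuStay(
        stay_id="rnd", site_id="t", age=50.0, sex="M", weight=weight,
        admission_source=source, discharge_time=discharge, era="derivation",
        creatinine=EventStream(ct, cv, "mg/dL"),
        urine=EventStream(ut, uv, "mL"), dialysis_times=dial,
    )
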