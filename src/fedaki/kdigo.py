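"""KDIGO 2012 acute kidney injury staging from creatinine, urine and dialysis.

Stage rules
-----------
Creatinine, evaluated at every measurement time t with value v:

* stage 1 — v minus the minimum value in the trailing 48-h window
  (t − 48, t] is >= 0.3 mg/dL, or v >= 1.5 x baseline;
* stage 2 — v >= 2.0 x baseline;
* stage 3 — v >= 3.0 x baseline, or v >= 4.0 mg/dL with a concurrent
  stage-1-qualifying acute rise (toggleable).

The fold-change criteria run on a 7-day clock anchored at the baseline
measurement (ward transfers) or the first available value (ED
admissions); set ``ratio_anchor="none"`` to drop the limit.

Urine output, evaluated at every charted time t against trailing windows:

* stage 1 — mean rate over (t − 6, t] below 0.5 mL/kg/h;
* stage 2 — mean rate over (t − 12, t] below 0.5 mL/kg/h;
* stage 3 — mean rate over (t − 24, t] below 0.3 mL/kg/h, or anuria
  (zero output) over (t − 12, t].

A trailing window only counts when charting covers it: gaps between
consecutive records larger than ``urine_gap_h`` (default 2 h) break the
span, so irregular charting cannot manufacture oliguria.

Any dialysis event during the stay is stage 3. All windows are half-open
(start, end]; times are decimal hours with admission at 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .errors import BaselineUnavailableError
from .types import AKIEvent, BaselineCreatinine, EventStream, IcuStay
from .types import in_group  # re-exported for convenience

__all__ = [
    "KdigoConfig",
    "baseline_creatinine",
    "stage_creatinine",
    "stage_urine",
    "label_aki",
    "in_group",
]


@dataclass(frozen=True)
class KdigoConfig:
    """Tunable constants of the staging rules (defaults follow KDIGO 2012)."""

    rise_threshold: float = 0.3  # mg/dL over the trailing 48 h
    rise_window_h: float = 48.0
    ratio_window_h: float = 168.0  # 7-day clock for fold-change criteria
    ratio_anchor: str = "baseline"  # "baseline" | "none"
    urine_gap_h: float = 2.0  # charting gap that breaks an oliguria span
    scr4_requires_acute_rise: bool = True
    oliguria_rate: float = 0.5  # mL/kg/h, stage 1 (>=6 h) and 2 (>=12 h)
    severe_oliguria_rate: float = 0.3  # mL/kg/h over >= 24 h, stage 3
    anuria_window_h: float = 12.0


DEFAULT_CONFIG = KdigoConfig()


def baseline_creatinine(stay: IcuStay,
                        config: KdigoConfig = DEFAULT_CONFIG) -> BaselineCreatinine:
    """Reference creatinine for the fold-change criteria.

    Ward transfers use the lowest pre-admission (t < 0) value; direct ED
    admissions use the first available value. Candidates >= 4 mg/dL are
    excluded. Raises BaselineUnavailableError when no candidate remains.
    """
    t = stay.creatinine.times
    v = stay.creatinine.values
    if stay.admission_source == "ward":
        m = (t < 0) & (v < 4.0)
        if not m.any():
            raise BaselineUnavailableError(
                f"stay {stay.stay_id}: no pre-admission creatinine < 4 mg/dL")
        i = int(np.flatnonzero(m)[np.argmin(v[m])])
        return BaselineCreatinine(float(v[i]), "pre_icu_lowest", float(t[i]))
    m = v < 4.0
    if not m.any():
        raise BaselineUnavailableError(
            f"stay {stay.stay_id}: no creatinine value < 4 mg/dL")
    i = int(np.flatnonzero(m)[0])
    return BaselineCreatinine(float(v[i]), "ed_first_available", float(t[i]))


def stage_creatinine(series: EventStream, baseline: BaselineCreatinine,
                     config: KdigoConfig = DEFAULT_CONFIG) -> List[Tuple[float, int]]:
    """Per-measurement maximum creatinine stage; times without a firing
    criterion are omitted."""
    t = series.times
    v = series.values
    n = t.size
    if n == 0:
        return []
    # trailing-window minimum (vectorised over the short series)
    in_win = (t[None, :] > t[:, None] - config.rise_window_h) & (t[None, :] <= t[:, None])
    vmat = np.where(in_win, v[None, :], np.inf)
    run_min = vmat.min(axis=1)
    acute_rise = (v - run_min) >= config.rise_threshold

    ratio = v / baseline.value
    if config.ratio_anchor == "baseline":
        on_clock = (t - baseline.anchor_time) <= config.ratio_window_h
    else:
        on_clock = np.ones(n, dtype=bool)
    r15 = (ratio >= 1.5) & on_clock
    r20 = (ratio >= 2.0) & on_clock
    r30 = (ratio >= 3.0) & on_clock

    s1_acute = acute_rise | r15
    abs4 = v >= 4.0
    if config.scr4_requires_acute_rise:
        abs4 = abs4 & s1_acute

    stage = np.zeros(n, dtype=int)
    stage[s1_acute] = 1
    stage[r20] = np.maximum(stage[r20], 2)
    stage[r30 | abs4] = 3
    return [(float(t[i]), int(stage[i])) for i in np.flatnonzero(stage)]


def _trailing_rate(times: np.ndarray, volumes: np.ndarray, window_h: float,
                   gap_h: float) -> np.ndarray:
    """Mean urine rate (mL/h) over (t - W, t] at each record time.

    NaN where charting does not cover the window: the window start must be
    reachable (some record at or before t - W + gap) and no gap between
    consecutive in-window records may exceed ``gap_h``.
    """
    n = times.size
    csum = np.concatenate([[0.0], np.cumsum(volumes)])
    j = np.arange(n)
    start = times - window_h
    i = np.searchsorted(times, start, side="right")  # first in-window index
    # charting must reach the window start: either a record exists at or
    # before it (entering gap bounded by gap_h), or charting begins inside
    # the window within one nominal charting hour of it
    covered = np.where(i > 0, times[i] - start <= gap_h,
                       times[i] - start <= 1.0)
    if n > 1:
        gaps = np.diff(times)
        # last position k with gaps[k] > gap_h among gaps[0..j-1]
        bad = np.where(gaps > gap_h, np.arange(n - 1), -1)
        last_bad = np.concatenate([[-1], np.maximum.accumulate(bad)])
        covered &= i > last_bad  # no interior gap inside the window
    rate = np.where(covered, (csum[j + 1] - csum[i]) / window_h, np.nan)
    return rate


def stage_urine(series: EventStream, weight: float,
                config: KdigoConfig = DEFAULT_CONFIG) -> List[Tuple[float, int]]:
    """Per-record maximum urine-output stage; non-firing times omitted."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    t = series.times
    v = series.values
    if t.size == 0:
        return []
    r6 = _trailing_rate(t, v, 6.0, config.urine_gap_h) / weight
    r12 = _trailing_rate(t, v, 12.0, config.urine_gap_h) / weight
    r24 = _trailing_rate(t, v, 24.0, config.urine_gap_h) / weight
    stage = np.zeros(t.size, dtype=int)
    with np.errstate(invalid="ignore"):
        stage[r6 < config.oliguria_rate] = 1
        stage[r12 < config.oliguria_rate] = 2
        anuria = (r12 == 0.0)
        stage[(r24 < config.severe_oliguria_rate) | anuria] = 3
    return [(float(t[i]), int(stage[i])) for i in np.flatnonzero(stage)]


def label_aki(stay: IcuStay,
              config: KdigoConfig = DEFAULT_CONFIG) -> Optional[AKIEvent]:
    """Label a stay's AKI onset, stage and triggering criterion.

    Onset is the earliest in-ICU time (0 <= t <= discharge) at which any
    criterion fires; stage is the maximum stage attained during the stay
    (any dialysis event forces stage 3). Ties at onset resolve in the
    order creatinine, urine, dialysis. Returns None for a clean stay.
    """
    baseline = baseline_creatinine(stay, config)
    firings: List[Tuple[float, int, str]] = []
    for time, stage in stage_creatinine(stay.creatinine, baseline, config):
        if 0 <= time <= stay.discharge_time:
            firings.append((time, stage, "creatinine"))
    for time, stage in stage_urine(stay.urine, stay.weight, config):
        if 0 <= time <= stay.discharge_time:
            firings.append((time, stage, "urine"))
    for time in stay.dialysis_times:
        if 0 <= time <= stay.discharge_time:
            firings.append((float(time), 3, "dialysis"))
    if not firings:
        return None
    priority = {"creatinine": 0, "urine": 1, "dialysis": 2}
    onset, _, criterion = min(firings, key=lambda f: (f[0], priority[f[2]]))
    stage = max(f[1] for f in firings)
    return AKIEvent(onset=onset, stage=stage, criterion=criterion)


def label_pre_admission(stay: IcuStay,
                        lookback_h: float = 168.0,
                        config: KdigoConfig = DEFAULT_CONFIG) -> Optional[AKIEvent]:
    """Apply the staging rules to pre-admission data only (t < 0).

    Used by the cohort exclusion "AKI occurred before the index ICU
    admission". Baseline rules are applied to the restricted record; a
    stay with no eligible pre-admission baseline cannot be labeled and
    returns None.
    """
    t = stay.creatinine.times
    m = (t < 0) & (t >= -lookback_h)
    sub = EventStream(t[m], stay.creatinine.values[m], stay.creatinine.unit)
    if len(sub) == 0:
        return None
    try:
        if stay.admission_source == "ward":
            baseline = baseline_creatinine(stay, config)
        else:
            v = sub.values[sub.values < 4.0]
            if v.size == 0:
                return None
            i = int(np.flatnonzero(sub.values < 4.0)[0])
            baseline = BaselineCreatinine(float(v[0]), "ed_first_available",
                                          float(sub.times[i]))
    except BaselineUnavailableError:
        return None
    firings = [(time, stage, "creatinine") for time, stage in
               stage_creatinine(sub, baseline, config) if time < 0]
    ut = stay.urine.times
    um = (ut < 0) & (ut >= -lookback_h)
    usub = EventStream(ut[um], stay.urine.values[um], stay.urine.unit)
    if len(usub):
        firings += [(time, stage, "urine") for time, stage in
                    stage_urine(usub, stay.weight, config) if time < 0]
    if not firings:
        return None
    onset, _, criterion = min(firings, key=lambda f: f[0])
    stage = max(f[1] for f in firings)
    return AKIEvent(onset=onset, stage=stage, criterion=criterion)
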