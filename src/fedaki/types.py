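"""Core in-memory containers shared across the pipeline.

Times are decimal hours on a per-stay clock with ICU admission at 0.
Pre-admission records (used for baseline creatinine and the
pre-admission AKI exclusion) carry negative times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "EventStream",
    "IcuStay",
    "BaselineCreatinine",
    "AKIEvent",
    "SEVERITY_GROUPS",
]


@dataclass
class EventStream:
    """Ordered (time, value) pairs for one charted variable.

    Missingness is the absence of records; streams never contain NaN.
    Urine streams hold volumes (mL) charted per interval; everything else
    holds point measurements in conventional units.
    """

    times: np.ndarray
    values: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("event times must be nondecreasing")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("event values must be finite")

    def __len__(self) -> int:
        return int(self.times.size)

    def between(self, start: float, end: float) -> "EventStream":
        """Records with time in the half-open window (start, end]."""
        m = (self.times > start) & (self.times <= end)
        return EventStream(self.times[m], self.values[m], self.unit)

    @classmethod
    def empty(cls, unit: str = "") -> "EventStream":
        return cls(np.empty(0), np.empty(0), unit)


@dataclass
class IcuStay:
    """One ICU admission with its attached event streams."""

    stay_id: str
    site_id: str
    age: float  # years
    sex: str  # "M" | "F"
    weight: float  # kg
    admission_source: str  # "ward" | "ED"
    discharge_time: float  # hours from admission
    era: str  # "derivation" | "temporal"
    esrd: bool = False
    prior_rrt: bool = False
    first_icu_admission: bool = True
    creatinine: EventStream = field(default_factory=lambda: EventStream.empty("mg/dL"))
    urine: EventStream = field(default_factory=lambda: EventStream.empty("mL"))
    vitals: dict = field(default_factory=dict)  # name -> EventStream
    labs: dict = field(default_factory=dict)  # name -> EventStream
    medications: list = field(default_factory=list)  # (drug_class, time_h)
    dialysis_times: list = field(default_factory=list)  # hours from admission
    #: generator ground truth (latents, true risk score); empty for real data
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.discharge_time <= 0:
            raise ValueError(f"stay {self.stay_id}: discharge_time must be > 0")

    def copy(self) -> "IcuStay":
        return replace(
            self,
            creatinine=EventStream(self.creatinine.times.copy(),
                                   self.creatinine.values.copy(),
                                   self.creatinine.unit),
            urine=EventStream(self.urine.times.copy(),
                              self.urine.values.copy(), self.urine.unit),
            vitals={k: EventStream(v.times.copy(), v.values.copy(), v.unit)
                    for k, v in self.vitals.items()},
            labs={k: EventStream(v.times.copy(), v.values.copy(), v.unit)
                  for k, v in self.labs.items()},
            medications=list(self.medications),
            dialysis_times=list(self.dialysis_times),
        )


@dataclass(frozen=True)
class BaselineCreatinine:
    """Reference creatinine for the fold-change criteria.

    provenance is ``pre_icu_lowest`` (ward transfers: lowest pre-admission
    value) or ``ed_first_available`` (direct ED admissions: earliest value).
    Candidates >= 4 mg/dL are never eligible.
    anchor_time is where the 7-day fold-change clock starts.
    """

    value: float
    provenance: str
    anchor_time: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.value < 4.0):
            raise ValueError("baseline creatinine must lie in (0, 4.0) mg/dL")


@dataclass(frozen=True)
class AKIEvent:
    onset: float  # hours from admission
    stage: int  # 1 | 2 | 3
    criterion: str  # "creatinine" | "urine" | "dialysis"

    def __post_init__(self) -> None:
        if self.stage not in (1, 2, 3):
            raise ValueError("stage must be 1, 2 or 3")
        if self.criterion not in ("creatinine", "urine", "dialysis"):
            raise ValueError(f"unknown criterion {self.criterion!r}")


#: Outcome severity groupings, nested: dialysis ⊆ stage3 ⊆ stage2_plus ⊆ all_stage.
SEVERITY_GROUPS = ("all_stage", "stage2_plus", "stage3", "dialysis")


def in_group(event: Optional[AKIEvent], grouping: str,
             had_dialysis: Optional[bool] = None) -> bool:
    """Membership of an AKI event in a severity grouping.

    ``dialysis`` is true when the stay's AKI course includes renal
    replacement therapy; pass had_dialysis explicitly when the triggering
    criterion alone does not decide it.
    """
    if grouping not in SEVERITY_GROUPS:
        raise ValueError(f"unknown severity grouping {grouping!r}")
    if event is None:
        return False
    if grouping == "all_stage":
        return True
    if grouping == "stage2_plus":
        return event.stage >= 2
    if grouping == "stage3":
        return event.stage == 3
    if had_dialysis is None:
        had_dialysis = event.criterion == "dialysis"
    return had_dialysis
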