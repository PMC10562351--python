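"""Study inclusion/exclusion rules and era partitioning.

Criteria are evaluated in a fixed order and each excluded stay is tallied
under the first criterion it matches, so the attrition flow is auditable:
n_included plus the per-criterion counts always sum to the input count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

from .errors import SchemaError
from .kdigo import label_pre_admission
from .types import IcuStay

__all__ = ["ExclusionTally", "apply_exclusions", "split_by_era"]

#: evaluation order (first match wins)
CRITERIA = ("age_lt_20", "esrd_on_rrt", "aki_before_icu",
            "hd_within_24h", "stay_lt_30h", "repeat_admission")


@dataclass
class ExclusionTally:
    counts: dict = field(default_factory=lambda: {c: 0 for c in CRITERIA})
    n_input: int = 0
    n_included: int = 0

    def check(self) -> None:
        if self.n_included + sum(self.counts.values()) != self.n_input:
            raise AssertionError("attrition tally does not balance")


def _require(stay: IcuStay, attr: str):
    value = getattr(stay, attr, None)
    if value is None:
        raise SchemaError(f"stay {stay.stay_id}: missing field {attr!r}")
    return value


def apply_exclusions(
    stays: Sequence[IcuStay],
    pre_admission_labeler: Optional[Callable[[IcuStay], object]] = None,
    pre_admission_lookback_h: float = 168.0,
) -> Tuple[List[IcuStay], ExclusionTally]:
    """Retain stays satisfying all inclusion rules, preserving input order.

    Rules: age >= 20; not (ESRD on renal replacement therapy); no AKI on
    pre-admission data (per the labeler, default KDIGO rules restricted to
    t < 0 within the lookback); no first hemodialysis within 24 h of
    admission; ICU stay >= 30 h (exactly 30.0 h is retained); first ICU
    admission only.
    """
    if pre_admission_labeler is None:
        def pre_admission_labeler(s: IcuStay):
            return label_pre_admission(s, lookback_h=pre_admission_lookback_h)

    tally = ExclusionTally(n_input=len(stays))
    included: List[IcuStay] = []
    for stay in stays:
        hit = None
        if _require(stay, "age") < 20:
            hit = "age_lt_20"
        elif _require(stay, "esrd") and _require(stay, "prior_rrt"):
            hit = "esrd_on_rrt"
        elif pre_admission_labeler(stay) is not None:
            hit = "aki_before_icu"
        elif (not stay.prior_rrt
              and any(0 <= t < 24.0 for t in stay.dialysis_times)):
            hit = "hd_within_24h"
        elif _require(stay, "discharge_time") < 30.0:
            hit = "stay_lt_30h"
        elif not _require(stay, "first_icu_admission"):
            hit = "repeat_admission"
        if hit is None:
            included.append(stay)
        else:
            tally.counts[hit] += 1
    tally.n_included = len(included)
    tally.check()
    return included, tally


def split_by_era(stays: Sequence[IcuStay]) -> Tuple[List[IcuStay], List[IcuStay]]:
    """Exhaustive, disjoint (derivation, temporal) partition by era tag."""
    derivation, temporal = [], []
    for stay in stays:
        era = getattr(stay, "era", None)
        if era == "derivation":
            derivation.append(stay)
        elif era == "temporal":
            temporal.append(stay)
        else:
            raise SchemaError(f"stay {stay.stay_id}: missing or unknown era "
                              f"tag {era!r}")
    return derivation, temporal
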