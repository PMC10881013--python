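"""Detection-threshold statistics from staircase reversals.

A session's detection threshold is the geometric mean of its reversal
concentrations, reported on the log10 scale.  Sessions that end before the
required reversal count are imputed so they still yield a bounded threshold:
floor terminations (subject cleared the lowest dilution) pad with the lowest
ladder fraction (0.03 by default) and welfare terminations pad with 0.80,
marking failure to complete the task.  Time-cap sessions are padded like
welfare ones by default — the protocol prescribes imputation only for floor
and welfare endings, so this choice is configurable and recorded in the
output's provenance fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from olfthresh.staircase import SessionResult, TerminationRules

__all__ = [
    "ThresholdRecord",
    "impute_reversals",
    "threshold_geomean",
    "session_threshold",
]


@dataclass(frozen=True)
class ThresholdRecord:
    """One dog x odor x condition log10 detection threshold with provenance."""

    dog: str
    odor: str
    condition: str
    log10_threshold: Optional[float]
    threshold_fraction: Optional[float]
    n_observed_reversals: int
    imputation: str  # none | floor | welfare | time_cap
    imputed_used: bool
    breed: str = ""
    group: str = ""
    day: Optional[int] = None

    @property
    def missing(self) -> bool:
        return self.log10_threshold is None


def impute_reversals(
    observed: Sequence[float],
    reason: str,
    n_required: int,
    floor_fraction: float = 0.03,
    fail_fraction: float = 0.80,
    time_cap_as_fail: bool = True,
) -> list[float]:
    """Pad a partial reversal list to ``n_required`` values.

    Floor terminations pad with ``floor_fraction``; welfare terminations pad
    with ``fail_fraction``; complete sessions pass through unchanged.
    Time-cap sessions pad with ``fail_fraction`` when ``time_cap_as_fail``
    (the default), else pass through unpadded.
    """
    observed = list(observed)
    if len(observed) > n_required:
        raise ValueError(
            f"{len(observed)} observed reversals exceed n_required={n_required}"
        )
    pad = n_required - len(observed)
    if reason == "reversals_complete":
        if pad:
            raise ValueError("reversals_complete session with too few reversals")
        return observed
    if reason == "floor":
        return observed + [floor_fraction] * pad
    if reason == "welfare":
        return observed + [fail_fraction] * pad
    if reason == "time_cap":
        if time_cap_as_fail:
            return observed + [fail_fraction] * pad
        return observed
    raise ValueError(f"unknown termination reason {reason!r}")


def threshold_geomean(reversal_fractions: Sequence[float]) -> tuple[float, float]:
    """Geometric mean of reversal concentrations.

    Returns ``(threshold_fraction, log10_threshold)`` where the log10
    threshold is the arithmetic mean of the log10 reversal fractions.
    """
    fracs = list(reversal_fractions)
    if not fracs:
        raise ValueError("cannot take the geometric mean of zero reversals")
    if any(f <= 0 for f in fracs):
        raise ValueError("reversal fractions must be positive")
    log10_thr = sum(math.log10(f) for f in fracs) / len(fracs)
    return 10.0**log10_thr, log10_thr


def session_threshold(
    session: SessionResult,
    rules: TerminationRules,
    impute: bool = True,
    floor_fraction: float = 0.03,
    fail_fraction: float = 0.80,
    time_cap_as_fail: bool = True,
    breed: str = "",
) -> ThresholdRecord:
    """Detection threshold of one session, with imputation provenance.

    With ``impute=False`` the geometric mean runs over the observed reversals
    only; a session with none yields a missing (flagged) record.
    """
    observed = session.observed_reversals
    reason = session.termination_reason
    imputed_used = impute and reason != "reversals_complete"

    if impute:
        values = impute_reversals(
            observed,
            reason,
            rules.reversals_required,
            floor_fraction=floor_fraction,
            fail_fraction=fail_fraction,
            time_cap_as_fail=time_cap_as_fail,
        )
    else:
        values = list(observed)

    if not values:
        return ThresholdRecord(
            dog=session.dog,
            odor=session.odor,
            condition=session.condition,
            log10_threshold=None,
            threshold_fraction=None,
            n_observed_reversals=0,
            imputation=reason if reason != "reversals_complete" else "none",
            imputed_used=False,
            breed=breed,
            group=session.group,
            day=session.day,
        )

    frac, log10_thr = threshold_geomean(values)
    return ThresholdRecord(
        dog=session.dog,
        odor=session.odor,
        condition=session.condition,
        log10_threshold=log10_thr,
        threshold_fraction=frac,
        n_observed_reversals=len(observed),
        imputation=reason if imputed_used else "none",
        imputed_used=imputed_used,
        breed=breed,
        group=session.group,
        day=session.day,
    )
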