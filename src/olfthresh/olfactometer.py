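"""Air-dilution model of the two-line olfactometer.

Stimulus intensity is the fraction of odor-line flow in the total delivered
flow.  The odor line is metered in cc/min and the clean (dilution) line in
L/min, so the clean flow is converted ×1000 before mixing — the convention
under which the instrument's flow settings reproduce its printed nominal
dilution ladder of 80 / 50 / 25 / 12 / 3 %.

Fractions are stored as unitless proportions in (0, 1]; percent appears only
at I/O.  Threshold arithmetic elsewhere in the package uses the *nominal* step
fractions (e.g. 0.12, not the flow-exact 0.1196), matching how incomplete
sessions are imputed at 0.03 and 0.80.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "DilutionStep",
    "DilutionLadder",
    "concentration_from_flows",
    "default_ladder",
    "NOMINAL_TOLERANCE",
]

#: maximum allowed gap between a step's flow-derived fraction and its nominal label
NOMINAL_TOLERANCE = 0.005


def concentration_from_flows(odor_flow: float, clean_flow: float) -> float:
    """Delivered odor fraction from the two flowmeter settings.

    Parameters
    ----------
    odor_flow : float
        Odor-line flow rate in cc/min; must be positive.
    clean_flow : float
        Clean (dilution) line flow rate in L/min; must be non-negative.

    Returns
    -------
    float
        Fraction of odor-line air in the total flow,
        ``odor_flow / (odor_flow + 1000 * clean_flow)``, in (0, 1].

    Examples
    --------
    >>> concentration_from_flows(1000, 0.25)
    0.8
    >>> round(concentration_from_flows(90, 2.91), 2)
    0.03
    """
    if odor_flow <= 0:
        raise ValueError(f"odor_flow must be positive, got {odor_flow}")
    if clean_flow < 0:
        raise ValueError(f"clean_flow must be non-negative, got {clean_flow}")
    return odor_flow / (odor_flow + 1000.0 * clean_flow)


@dataclass(frozen=True)
class DilutionStep:
    """One rung of the dilution ladder.

    ``nominal_fraction`` is the label the instrument is operated under (e.g.
    0.12); ``actual_fraction`` is derived from the flows and must agree with
    the nominal label to within ``NOMINAL_TOLERANCE``.
    """

    step_number: int
    odor_flow: float  # cc/min
    clean_flow: float  # L/min
    nominal_fraction: float

    def __post_init__(self) -> None:
        if not (0 < self.nominal_fraction <= 1):
            raise ValueError(
                f"nominal_fraction must be in (0, 1], got {self.nominal_fraction}"
            )
        actual = concentration_from_flows(self.odor_flow, self.clean_flow)
        if abs(actual - self.nominal_fraction) > NOMINAL_TOLERANCE:
            raise ValueError(
                f"step {self.step_number}: flow-derived fraction {actual:.4f} "
                f"disagrees with nominal {self.nominal_fraction:.4f} by more "
                f"than {NOMINAL_TOLERANCE}"
            )

    @property
    def actual_fraction(self) -> float:
        """Flow-derived odor fraction, in (0, 1]."""
        return concentration_from_flows(self.odor_flow, self.clean_flow)


@dataclass(frozen=True)
class DilutionLadder:
    """Ordered dilution steps, highest concentration first."""

    steps: tuple[DilutionStep, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("ladder must contain at least one step")
        numbers = [s.step_number for s in self.steps]
        if len(set(numbers)) != len(numbers):
            raise ValueError("step_numbers must be unique")
        fracs = [s.nominal_fraction for s in self.steps]
        if any(b >= a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("nominal fractions must be strictly decreasing")

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self) -> Iterable[DilutionStep]:
        return iter(self.steps)

    @property
    def fractions(self) -> tuple[float, ...]:
        """Nominal fractions, highest first."""
        return tuple(s.nominal_fraction for s in self.steps)

    def fraction_at(self, index: int) -> float:
        """Nominal fraction at 0-based ladder index (0 = highest)."""
        return self.steps[index].nominal_fraction

    @classmethod
    def from_fractions(cls, fractions: Sequence[float]) -> "DilutionLadder":
        """Build a ladder from nominal fractions alone (synthetic flows).

        Convenience for simulation studies with ladders other than the
        instrument default; each step gets a consistent pair of flows
        (odor line fixed at 1000 cc/min).
        """
        steps = []
        for i, f in enumerate(fractions, start=1):
            if not (0 < f <= 1):
                raise ValueError(f"fraction must be in (0, 1], got {f}")
            # solve clean_flow so that the flow-derived fraction equals f exactly
            clean = 1000.0 * (1.0 - f) / (1000.0 * f)
            steps.append(
                DilutionStep(
                    step_number=i, odor_flow=1000.0, clean_flow=clean, nominal_fraction=f
                )
            )
        return cls(steps=tuple(steps))


#: (step, odor cc/min, clean L/min, nominal fraction) of the instrument ladder
_DEFAULT_ROWS = (
    (1, 1000.0, 0.25, 0.80),
    (2, 1000.0, 1.00, 0.50),
    (3, 750.0, 2.25, 0.25),
    (4, 360.0, 2.65, 0.12),
    (5, 90.0, 2.91, 0.03),
)


def default_ladder() -> DilutionLadder:
    """The instrument's five-step ladder: 80, 50, 25, 12 and 3 % odor flow."""
    return DilutionLadder(
        steps=tuple(DilutionStep(n, o, c, f) for n, o, c, f in _DEFAULT_ROWS)
    )
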