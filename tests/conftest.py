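"""Shared fixtures and the independent staircase replay oracle."""

from __future__ import annotations

import numpy as np
import pytest

from olfthresh.olfactometer import DilutionLadder, default_ladder
from olfthresh.staircase import TerminationRules


@pytest.fixture
def ladder() -> DilutionLadder:
    return default_ladder()


@pytest.fixture
def rules7() -> TerminationRules:
    return TerminationRules(reversals_required=7)


@pytest.fixture
def rules4() -> TerminationRules:
    return TerminationRules(reversals_required=4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def replay_oracle(
    outcomes: list[str], fractions: list[float]
) -> tuple[list[int], list[float]]:
    """Straightforward replay of the 3-down-1-up rules, written independently
    of the state machine: returns (step trajectory after each trial, reversal
    fractions).  Position 0 is the highest concentration.
    """
    pos = 0
    lowest = len(fractions) - 1
    streak = 0
    direction = 0  # 0 unset, -1 descending, +1 ascending
    trajectory: list[int] = []
    reversals: list[float] = []
    for oc in outcomes:
        if oc == "correct":
            streak += 1
            if streak == 3:
                if pos < lowest:
                    if direction == +1:
                        reversals.append(fractions[pos])
                    pos += 1
                    direction = -1
                    streak = 0
                # at the floor the streak holds (floor termination pending)
        elif oc == "incorrect":
            streak = 0
            if pos > 0:
                if direction == -1:
                    reversals.append(fractions[pos])
                pos -= 1
                direction = +1
        elif oc == "no_search":
            pass
        else:  # pragma: no cover - defensive
            raise ValueError(oc)
        trajectory.append(pos)
    return trajectory, reversals
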