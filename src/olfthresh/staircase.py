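"""3-AFC, 3-down-1-up staircase engine.

The subject faces three odor ports, exactly one carrying the target, and the
dilution steps down one rung after three consecutive correct choices and up
one rung after any error.  A *reversal* is any change in the direction of
concentration adjustment; sessions normally end once a required number of
reversals has accumulated, but can also end by clearing the floor (three
consecutive correct at the lowest step), by a session time cap, or by welfare
criteria (refusal to search).

Conventions (the procedure itself underdetermines these):

* The reversal concentration is the fraction presented on the trial that
  *triggered* the direction change; symmetric for up- and down-turns.  The
  alternative (post-change) convention is available via
  ``reversal_at_new_step=True`` on :func:`update_state` / :func:`run_session`.
* The correct-counter resets on every realized step change and on every
  error; partial credit never carries across a step change.
* An error at the top step is clamped: no movement, hence no reversal.
* The first realized movement sets the direction and is never itself a
  reversal.
* No-search trials do not move the concentration and do not reset the
  correct-counter; they only feed the welfare criteria.
* When the floor rule and the reversal count would both fire on the same
  trial, the floor wins (floor sessions are imputed downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Literal, Optional, Sequence

import numpy as np

from olfthresh.olfactometer import DilutionLadder

__all__ = [
    "Outcome",
    "StaircaseState",
    "TerminationRules",
    "TrialRecord",
    "SessionResult",
    "update_state",
    "check_termination",
    "run_session",
    "TimingModel",
]

Outcome = Literal["correct", "incorrect", "no_search"]
Direction = Literal["none", "down", "up"]
TerminationReason = Literal["reversals_complete", "floor", "time_cap", "welfare"]

_OUTCOMES = ("correct", "incorrect", "no_search")


@dataclass(frozen=True)
class StaircaseState:
    """Live state of a 3-down-1-up session.

    ``current_step`` is a 0-based index into the ladder (0 = highest
    concentration).  ``reversals`` holds the fractions at which each recorded
    reversal occurred, in order.
    """

    current_step: int = 0
    consecutive_correct: int = 0
    last_direction: Direction = "none"
    reversals: tuple[float, ...] = ()
    trials_elapsed: int = 0
    no_search_streak: int = 0
    heat_stress: bool = False


@dataclass(frozen=True)
class TerminationRules:
    """Session termination thresholds.

    ``reversals_required`` is 7 for the single-session threshold protocol and
    4 for the daily acclimatization protocol; the remaining defaults are the
    shared welfare/floor/time rules.
    """

    reversals_required: int = 7
    floor_consecutive: int = 3
    session_cap_min: float = 40.0
    welfare_no_search: int = 5
    welfare_no_search_with_heat_stress: int = 1

    def __post_init__(self) -> None:
        for name in (
            "reversals_required",
            "floor_consecutive",
            "session_cap_min",
            "welfare_no_search",
            "welfare_no_search_with_heat_stress",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TrialRecord:
    """One presented trial: what was shown, what happened, and when."""

    trial_index: int
    presented_step: int  # 0-based ladder index
    presented_fraction: float
    outcome: Outcome
    latency_s: Optional[float]  # None on no-search trials
    inter_box_intervals_s: tuple[float, ...] = ()
    trial_start_s: float = 0.0


@dataclass(frozen=True)
class SessionResult:
    """A completed session: the full trial log plus how and why it ended."""

    dog: str
    odor: str
    condition: str
    trials: tuple[TrialRecord, ...]
    observed_reversals: tuple[float, ...]
    termination_reason: TerminationReason
    session_duration_min: float
    group: str = ""
    day: Optional[int] = None


def update_state(
    state: StaircaseState,
    outcome: Outcome,
    ladder: DilutionLadder,
    reversal_at_new_step: bool = False,
) -> StaircaseState:
    """Advance the staircase by one completed trial.

    Returns a new state; the input state is unchanged.  ``reversal_at_new_step``
    switches the reversal-concentration convention from the triggering trial's
    fraction (default) to the post-change fraction.
    """
    if outcome not in _OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    if not (0 <= state.current_step < len(ladder)):
        raise ValueError(f"state step {state.current_step} outside ladder")

    trials = state.trials_elapsed + 1

    if outcome == "no_search":
        return replace(
            state,
            trials_elapsed=trials,
            no_search_streak=state.no_search_streak + 1,
        )

    lowest = len(ladder) - 1
    step = state.current_step
    cc = state.consecutive_correct
    direction = state.last_direction
    reversals = state.reversals

    if outcome == "correct":
        cc += 1
        if cc >= 3:
            if step < lowest:
                moved: Direction = "down"
                if direction == "up":
                    mark = step + 1 if reversal_at_new_step else step
                    reversals = reversals + (ladder.fraction_at(mark),)
                step += 1
                cc = 0
                direction = moved
            # at the floor: counter holds at 3 pending the floor-termination check
            else:
                cc = 3
        return replace(
            state,
            current_step=step,
            consecutive_correct=cc,
            last_direction=direction,
            reversals=reversals,
            trials_elapsed=trials,
            no_search_streak=0,
        )

    # incorrect
    cc = 0
    if step > 0:
        if direction == "down":
            mark = step - 1 if reversal_at_new_step else step
            reversals = reversals + (ladder.fraction_at(mark),)
        step -= 1
        direction = "up"
    # clamped at the top: no movement, no direction change
    return replace(
        state,
        current_step=step,
        consecutive_correct=cc,
        last_direction=direction,
        reversals=reversals,
        trials_elapsed=trials,
        no_search_streak=0,
    )


def check_termination(
    state: StaircaseState,
    rules: TerminationRules,
    elapsed_min: float,
    ladder: DilutionLadder,
) -> Optional[TerminationReason]:
    """Return the termination reason, or None if the session continues.

    Priority: welfare > floor > reversals_complete > time_cap.
    """
    if state.no_search_streak >= rules.welfare_no_search or (
        state.heat_stress
        and state.no_search_streak >= rules.welfare_no_search_with_heat_stress
    ):
        return "welfare"
    if (
        state.current_step == len(ladder) - 1
        and state.consecutive_correct >= rules.floor_consecutive
    ):
        return "floor"
    if len(state.reversals) >= rules.reversals_required:
        return "reversals_complete"
    if elapsed_min >= rules.session_cap_min:
        return "time_cap"
    return None


@dataclass
class TimingModel:
    """Per-trial timing for simulated sessions.

    Latencies and inter-box intervals are lognormal; each trial's duration is
    latency + search time + the inter-trial purge interval.  ``mu_*`` are
    natural-log locations for the lognormals; ``heat_shift_s`` slows both
    measures additively in log-space (per unit of a 0–1 heat index).
    """

    mu_latency: float = np.log(3.0)
    sigma_latency: float = 0.4
    mu_ibi: float = np.log(1.5)
    sigma_ibi: float = 0.4
    heat_index: float = 0.0
    heat_shift: float = 0.35  # log-s shift at heat_index=1
    inter_trial_s: float = 20.0
    search_s: float = 6.0

    def draw(self, rng: np.random.Generator) -> tuple[float, tuple[float, ...]]:
        """Draw (latency_s, inter_box_intervals_s) for one searched trial."""
        shift = self.heat_shift * self.heat_index
        lat = float(rng.lognormal(self.mu_latency + shift, self.sigma_latency))
        n_ibi = int(rng.integers(1, 3))  # 2-3 pokes per trial
        ibis = tuple(
            float(rng.lognormal(self.mu_ibi + shift, self.sigma_ibi))
            for _ in range(n_ibi)
        )
        return lat, ibis

    def trial_duration_s(self, latency_s: Optional[float], ibis: Sequence[float]) -> float:
        lat = latency_s if latency_s is not None else self.search_s
        return lat + sum(ibis) + self.search_s + self.inter_trial_s


def run_session(
    observer: Callable[[float, np.random.Generator], Outcome],
    ladder: DilutionLadder,
    rules: TerminationRules,
    rng: np.random.Generator,
    timing_model: Optional[TimingModel] = None,
    dog: str = "dog",
    odor: str = "odor",
    condition: str = "standard",
    heat_stress: bool = False,
    reversal_at_new_step: bool = False,
    group: str = "",
    day: Optional[int] = None,
    max_trials: int = 10_000,
) -> SessionResult:
    """Run one staircase session against an observer.

    ``observer`` maps (presented fraction, rng) to an outcome; see
    :class:`olfthresh.synthetic_data.Observer` for the psychometric one.
    Starts at the highest concentration; deterministic given the rng seed.
    ``max_trials`` is a simulation safety valve only — real sessions end by
    the rules long before it.
    """
    if rules.reversals_required <= 0:
        raise ValueError("reversals_required must be positive")
    timing = timing_model or TimingModel()
    state = StaircaseState(heat_stress=heat_stress)
    trials: list[TrialRecord] = []
    t_s = 0.0
    reason: Optional[TerminationReason] = None

    while reason is None and len(trials) < max_trials:
        frac = ladder.fraction_at(state.current_step)
        outcome = observer(frac, rng)
        if outcome == "no_search":
            latency, ibis = None, ()
        else:
            latency, ibis = timing.draw(rng)
        trials.append(
            TrialRecord(
                trial_index=len(trials),
                presented_step=state.current_step,
                presented_fraction=frac,
                outcome=outcome,
                latency_s=latency,
                inter_box_intervals_s=ibis,
                trial_start_s=t_s,
            )
        )
        t_s += timing.trial_duration_s(latency, ibis)
        state = update_state(state, outcome, ladder, reversal_at_new_step)
        reason = check_termination(state, rules, t_s / 60.0, ladder)

    if reason is None:  # max_trials safety valve
        reason = "time_cap"
    return SessionResult(
        dog=dog,
        odor=odor,
        condition=condition,
        trials=tuple(trials),
        observed_reversals=state.reversals,
        termination_reason=reason,
        session_duration_min=t_s / 60.0,
        group=group,
        day=day,
    )
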