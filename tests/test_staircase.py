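"""Staircase state machine vs. an independent replay oracle, plus termination."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from olfthresh.staircase import (
    StaircaseState,
    TerminationRules,
    check_termination,
    run_session,
    update_state,
)

from conftest import replay_oracle


def drive(outcomes, ladder):
    state = StaircaseState()
    states = []
    for oc in outcomes:
        state = update_state(state, oc, ladder)
        states.append(state)
    return states


# ---------------------------------------------------------------------------
# transition examples


def test_three_correct_descends_without_reversal(ladder):
    state = StaircaseState(current_step=0, consecutive_correct=2, last_direction="none")
    new = update_state(state, "correct", ladder)
    assert new.current_step == 1
    assert new.consecutive_correct == 0
    assert new.last_direction == "down"
    assert new.reversals == ()


def test_error_after_descent_records_reversal_at_triggering_fraction(ladder):
    state = StaircaseState(current_step=2, consecutive_correct=0, last_direction="down")
    new = update_state(state, "incorrect", ladder)
    assert new.current_step == 1
    assert new.last_direction == "up"
    assert new.reversals == (0.25,)


def test_error_at_top_is_clamped(ladder):
    state = StaircaseState(current_step=0)
    new = update_state(state, "incorrect", ladder)
    assert new.current_step == 0
    assert new.last_direction == "none"
    assert new.reversals == ()


def test_no_search_freezes_staircase_and_counts_streak(ladder):
    state = StaircaseState(current_step=1, consecutive_correct=2, last_direction="down")
    new = update_state(state, "no_search", ladder)
    assert new.current_step == 1
    assert new.consecutive_correct == 2  # streak preserved
    assert new.no_search_streak == 1
    searched = update_state(new, "correct", ladder)
    assert searched.no_search_streak == 0


def test_unknown_outcome_rejected(ladder):
    with pytest.raises(ValueError):
        update_state(StaircaseState(), "maybe", ladder)


def test_mixed_sequence_reversal_count_matches_oracle(ladder):
    # CCC CCC W CCC W: descend twice, error (rev 1), descend (rev 2), error (rev 3)
    outcomes = ["correct"] * 3 + ["correct"] * 3 + ["incorrect"] + ["correct"] * 3 + ["incorrect"]
    states = drive(outcomes, ladder)
    _, oracle_revs = replay_oracle(outcomes, list(ladder.fractions))
    assert list(states[-1].reversals) == oracle_revs
    assert len(states[-1].reversals) == 3


# ---------------------------------------------------------------------------
# oracle equivalence and reversal parity


def test_exhaustive_oracle_equivalence_short_sequences(ladder):
    """State machine agrees with the replay oracle on every correct/incorrect
    sequence up to length 10 (step trajectory and reversal fractions)."""
    fractions = list(ladder.fractions)
    for n in range(1, 11):
        for bits in itertools.product([0, 1], repeat=n):
            outcomes = ["correct" if b else "incorrect" for b in bits]
            states = drive(outcomes, ladder)
            trajectory = [s.current_step for s in states]
            oracle_traj, oracle_revs = replay_oracle(outcomes, fractions)
            assert trajectory == oracle_traj, outcomes
            assert list(states[-1].reversals) == oracle_revs, outcomes


@given(st.lists(st.sampled_from(["correct", "incorrect", "no_search"]), max_size=60))
@settings(derandomize=True, max_examples=300, deadline=None)
def test_random_sequences_stay_in_bounds_and_alternate(outcomes):
    from olfthresh.olfactometer import default_ladder

    lad = default_ladder()
    states = drive(outcomes, lad)
    for s in states:
        assert 0 <= s.current_step < len(lad)
        assert s.consecutive_correct <= 3
    # successive reversal fractions must alternate direction strictly
    revs = states[-1].reversals if states else ()
    diffs = [b - a for a, b in zip(revs, revs[1:])]
    assert all(d != 0 for d in diffs)
    assert all(d1 * d2 < 0 for d1, d2 in zip(diffs, diffs[1:]))


# ---------------------------------------------------------------------------
# termination


def test_termination_priority_and_rules(ladder, rules7):
    complete = StaircaseState(reversals=(0.25,) * 7)
    assert check_termination(complete, rules7, 10.0, ladder) == "reversals_complete"

    floor = StaircaseState(current_step=4, consecutive_correct=3)
    assert check_termination(floor, rules7, 10.0, ladder) == "floor"

    welfare = StaircaseState(no_search_streak=5)
    assert check_termination(welfare, rules7, 10.0, ladder) == "welfare"

    heat = StaircaseState(no_search_streak=1, heat_stress=True)
    assert check_termination(heat, rules7, 10.0, ladder) == "welfare"

    timecap = StaircaseState(reversals=(0.25,) * 6)
    assert check_termination(timecap, rules7, 40.0, ladder) == "time_cap"

    # welfare trumps floor trumps reversals
    everything = StaircaseState(
        current_step=4, consecutive_correct=3, reversals=(0.03,) * 7, no_search_streak=5
    )
    assert check_termination(everything, rules7, 50.0, ladder) == "welfare"
    floor_and_done = StaircaseState(
        current_step=4, consecutive_correct=3, reversals=(0.03,) * 7
    )
    assert check_termination(floor_and_done, rules7, 50.0, ladder) == "floor"

    ongoing = StaircaseState(reversals=(0.25,) * 3)
    assert check_termination(ongoing, rules7, 10.0, ladder) is None


# ---------------------------------------------------------------------------
# session runner


def test_perfect_observer_floors_in_fifteen_trials(ladder, rules7, rng):
    res = run_session(lambda f, r: "correct", ladder, rules7, rng)
    assert res.termination_reason == "floor"
    assert len(res.trials) == 15  # 3 per step x 5 steps
    assert res.observed_reversals == ()


def test_hopeless_observer_times_out_at_top(ladder, rules7, rng):
    res = run_session(lambda f, r: "incorrect", ladder, rules7, rng)
    assert res.termination_reason == "time_cap"
    assert all(t.presented_step == 0 for t in res.trials)
    assert res.session_duration_min >= rules7.session_cap_min


def test_step_function_observer_reverses_between_its_edges(ladder, rules7, rng):
    # perfect down to 0.25, hopeless below: all reversals at 0.12 and 0.25
    observer = lambda f, r: "correct" if f >= 0.25 else "incorrect"
    res = run_session(observer, ladder, rules7, rng)
    assert res.termination_reason == "reversals_complete"
    assert set(res.observed_reversals) == {0.12, 0.25}


def test_session_deterministic_given_seed(ladder, rules7):
    from olfthresh.synthetic_data import Observer

    obs = Observer(alpha=-0.9, beta=0.15)
    r1 = run_session(obs, ladder, rules7, np.random.default_rng(7))
    r2 = run_session(obs, ladder, rules7, np.random.default_rng(7))
    assert r1 == r2


def test_no_search_observer_triggers_welfare(ladder, rules7, rng):
    res = run_session(lambda f, r: "no_search", ladder, rules7, rng)
    assert res.termination_reason == "welfare"
    assert len(res.trials) == rules7.welfare_no_search


def test_bad_rules_rejected(ladder, rng):
    with pytest.raises(ValueError):
        TerminationRules(reversals_required=0)
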