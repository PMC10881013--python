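"""Synthetic observers and full synthetic experiments.

Generates trial-level datasets with the statistical structure the analysis
layer assumes, so the whole pipeline is testable at desk scale without the
original supplementary files:

* a 3-AFC psychometric observer — logistic in log10 concentration with a
  guess floor of 1/3, a lapse ceiling, midpoint ``alpha`` and spread
  ``beta``;
* condition- and odor-specific log-threshold shifts with a per-dog random
  intercept and session noise;
* the two study designs: a crossed 8-dog x 4-odor x 5-condition single
  session experiment (with counterbalanced condition orders) and a 22-day
  two-group acclimatization experiment with a 6-day temperature/humidity
  ramp and hot-condition test days;
* session temperature trajectories (exponential approach to a
  condition-specific asymptote, read ~every 5 minutes) and lognormal
  latency / inter-box-interval timings whose location shifts with a
  condition heat index and with the observer's performance deficit, so the
  covariate analyses have signal to recover.

One master seed drives everything; per-session child seeds are derived
deterministically so any single session is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from olfthresh.behavior_metrics import TemperatureSeries, mean_session_temperature
from olfthresh.olfactometer import DilutionLadder, default_ladder
from olfthresh.staircase import (
    Outcome,
    SessionResult,
    TerminationRules,
    TimingModel,
    run_session,
)
from olfthresh.thresholds import session_threshold

__all__ = [
    "Observer",
    "EffectSpec",
    "DesignSpec",
    "SimulatedExperiment",
    "p_correct",
    "staircase_equilibrium_accuracy",
    "temp_trajectory",
    "simulate_experiment1",
    "simulate_experiment2",
    "ODORS",
    "CONDITIONS",
    "CONDITION_ORDERS",
]

# ---------------------------------------------------------------------------
# psychometric observer

N_ALTERNATIVES = 3


@dataclass(frozen=True)
class Observer:
    """3-AFC psychometric observer.

    P(correct | fraction) = gamma + (1 - gamma - lapse) * F((log10 f - alpha)/beta)
    with F the standard logistic, ``gamma`` the 1/3 guess floor, ``alpha``
    the log10 concentration of the psychometric midpoint and ``beta`` the
    logistic spread in log10 units.  ``p_no_search`` is the per-trial
    probability of refusing to search (a welfare-relevant behavior, not a
    perceptual one).
    """

    alpha: float
    beta: float = 0.15
    guess: float = 1.0 / N_ALTERNATIVES
    lapse: float = 0.02
    p_no_search: float = 0.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not (0 <= self.lapse <= 0.1):
            raise ValueError("lapse must be in [0, 0.1]")

    def p_correct(self, fraction: float) -> float:
        return p_correct(self, fraction)

    def __call__(self, fraction: float, rng: np.random.Generator) -> Outcome:
        if self.p_no_search > 0 and rng.random() < self.p_no_search:
            return "no_search"
        return "correct" if rng.random() < self.p_correct(fraction) else "incorrect"


def p_correct(observer: Observer, fraction: float) -> float:
    """Probability of a correct 3-AFC choice at the given odor fraction."""
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    x = (math.log10(fraction) - observer.alpha) / observer.beta
    f = 1.0 / (1.0 + math.exp(-x))
    return observer.guess + (1.0 - observer.guess - observer.lapse) * f


def staircase_equilibrium_accuracy() -> float:
    """Accuracy the 3-down-1-up rule converges to: p with p^3 = 1/2.

    Descent requires three consecutive correct (probability p^3); ascent
    follows any error.  The staircase equilibrates where these balance,
    p = 0.5^(1/3) ~ 0.794.
    """
    return 0.5 ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# study design descriptors

ODORS = ("AN", "C4", "SP", "TNT")

#: condition label -> (temperature degC, relative humidity %)
CONDITIONS = {
    "standard": (21.0, 50.0),
    "HTHH": (40.0, 70.0),
    "HTLH": (40.0, 40.0),
    "LTHH": (0.0, 90.0),
    "LTLH": (0.0, 50.0),
}

#: counterbalanced condition orders, (group, odor) -> order after the first
#: standard session
CONDITION_ORDERS = {
    ("A", "C4"): ("standard", "LTHH", "HTHH", "HTLH", "LTLH"),
    ("B", "C4"): ("standard", "HTLH", "LTLH", "LTHH", "HTHH"),
    ("A", "SP"): ("standard", "HTLH", "LTHH", "LTLH", "HTHH"),
    ("B", "SP"): ("standard", "LTHH", "HTLH", "HTHH", "LTLH"),
    ("A", "AN"): ("standard", "HTHH", "LTLH", "LTHH", "HTLH"),
    ("B", "AN"): ("standard", "LTHH", "HTHH", "LTLH", "HTLH"),
    ("A", "TNT"): ("standard", "LTHH", "HTHH", "HTLH", "LTLH"),
    ("B", "TNT"): ("standard", "HTHH", "HTLH", "LTLH", "LTHH"),
}

#: odor testing order (each odor run to completion before the next)
ODOR_ORDER = ("C4", "SP", "AN", "TNT")

#: 0-1 heat load index per condition, used by timing and no-search models
HEAT_INDEX = {
    "standard": 0.0,
    "HTHH": 1.0,
    "HTLH": 0.7,
    "LTHH": 0.15,
    "LTLH": 0.1,
}

#: subcutaneous temperature asymptote per condition (degC); cold-condition
#: readings are sensor artefacts, emitted with valid=False
TEMP_ASYMPTOTE = {
    "standard": 39.2,
    "HTHH": 40.8,
    "HTLH": 40.1,
    "LTHH": 33.0,
    "LTLH": 33.5,
}
TEMP_VALID = {
    "standard": True,
    "HTHH": True,
    "HTLH": True,
    "LTHH": False,
    "LTLH": False,
}

#: per-trial probability of refusing to search, by condition
P_NO_SEARCH = {
    "standard": 0.005,
    "HTHH": 0.04,
    "HTLH": 0.02,
    "LTHH": 0.01,
    "LTLH": 0.01,
}


def exp2_setpoint(day: int, group: str) -> tuple[float, float, str]:
    """(temperature, RH, condition label) for an acclimatization-study day.

    Days 11 and 22 are hot test days for both groups; the acclimatization
    group ramps from standard to the hot condition over days 1-6 and stays
    there; the control group trains at standard throughout.  Day 0 is the
    baseline standard-condition test for both groups.
    """
    if day in (11, 22):
        return (*CONDITIONS["HTHH"], "HTHH")
    if day == 0 or group == "control":
        return (*CONDITIONS["standard"], "standard")
    ramp = {1: (21.0, 50.0), 2: (24.0, 53.0), 3: (28.0, 56.0),
            4: (31.0, 59.0), 5: (34.0, 62.0), 6: (38.0, 65.0)}
    if day in ramp:
        t, rh = ramp[day]
        label = "standard" if day == 1 else f"ramp_{t:.0f}C_{rh:.0f}RH"
        return (t, rh, label)
    return (*CONDITIONS["HTHH"], "HTHH")


@dataclass(frozen=True)
class DesignSpec:
    """Who is tested, on what, in which order.

    Eight dogs, four per breed; order groups A/B counterbalance condition
    order within each odor.  The acclimatization study splits the same dogs
    into control and acclimatization groups of four.
    """

    dogs: tuple[str, ...] = tuple(f"dog{i}" for i in range(1, 9))
    breeds: tuple[str, ...] = ("LAB",) * 4 + ("GSP",) * 4
    order_groups: tuple[str, ...] = ("A", "A", "B", "B", "A", "A", "B", "B")
    odors: tuple[str, ...] = ODORS
    conditions: tuple[str, ...] = tuple(CONDITIONS)
    exp2_groups: tuple[str, ...] = (
        "control", "control", "acclimatization", "acclimatization",
        "control", "control", "acclimatization", "acclimatization",
    )
    exp2_days: tuple[int, ...] = tuple(range(0, 23))
    exp2_test_days: tuple[int, ...] = (11, 22)

    def breed_of(self, dog: str) -> str:
        return self.breeds[self.dogs.index(dog)]

    def order_group_of(self, dog: str) -> str:
        return self.order_groups[self.dogs.index(dog)]

    def exp2_group_of(self, dog: str) -> str:
        return self.exp2_groups[self.dogs.index(dog)]


# Condition shifts (log10 units, relative to standard) planted by default.
# C4's hot-condition shifts are the study's headline contrasts; the others
# follow the observed per-condition mean differences; the most volatile
# odorant (SP) sits below the ladder floor so shifts are unresolvable.
_DEFAULT_SHIFTS = {
    ("C4", "HTHH"): 0.47,
    ("C4", "HTLH"): 0.38,
    ("C4", "LTHH"): 0.20,
    ("C4", "LTLH"): 0.01,
    ("AN", "HTHH"): 0.38,
    ("AN", "HTLH"): 0.28,
    ("AN", "LTHH"): 0.28,
    ("AN", "LTLH"): -0.17,
    ("TNT", "HTHH"): 0.26,
    ("TNT", "HTLH"): -0.09,
    ("TNT", "LTHH"): 0.32,
    ("TNT", "LTLH"): 0.0,
}


def _default_baselines() -> dict[str, float]:
    # standard-condition log10 detection levels; SP is below the ladder floor
    return {"AN": -0.73, "C4": -1.40, "SP": -2.00, "TNT": -0.79}


def _default_shifts() -> dict[tuple[str, str], float]:
    return dict(_DEFAULT_SHIFTS)


@dataclass(frozen=True)
class EffectSpec:
    """Ground truth for the synthetic observers.

    The session observer midpoint is

        alpha = baseline[odor] + shift[(odor, condition)] + dog_effect
                + temp_slope * (mean_temp - temp_ref)   [hot/standard only]
                + group_effect * 1[acclimatized, test day]   [daily study]
                + N(0, sigma_session)

    ``shift`` plants condition effects directly; ``temp_slope`` (default 0)
    plants a subcutaneous-temperature-mediated pathway instead — the two
    should not both be non-zero for the same contrast or the planted
    condition effect is double-counted.  The lapse rate rises with session
    mean temperature above ``lapse_temp_ref``.
    """

    baseline_alpha: dict[str, float] = field(default_factory=_default_baselines)
    condition_shift: dict[tuple[str, str], float] = field(default_factory=_default_shifts)
    sigma_dog: float = 0.15
    sigma_session: float = 0.10
    beta: float = 0.15
    lapse0: float = 0.02
    lapse_per_degc: float = 0.02
    lapse_temp_ref: float = 39.5
    temp_slope: float = 0.0  # log10 per degC of session mean subcutaneous temp
    temp_ref: float = 39.2
    group_effect: float = -0.50  # acclimatization - control on hot test days
    perf_timing_coef: float = 0.5  # log-s slowdown per log10 unit of deficit

    def shift(self, odor: str, condition: str) -> float:
        return self.condition_shift.get((odor, condition), 0.0)

    def lapse_at(self, mean_temp: Optional[float]) -> float:
        lam = self.lapse0
        if mean_temp is not None:
            lam += self.lapse_per_degc * max(0.0, mean_temp - self.lapse_temp_ref)
        return min(max(lam, 0.0), 0.1)


# ---------------------------------------------------------------------------
# temperature trajectories


def temp_trajectory(
    condition: str,
    minutes: Sequence[float],
    rng: np.random.Generator,
    dog: str = "dog",
    t0: float = 38.5,
    tau_min: float = 12.0,
    noise_sd: float = 0.15,
    asymptote: Optional[float] = None,
) -> TemperatureSeries:
    """Subcutaneous temperature readings over a session.

    Exponential approach ``T(t) = T_asym - (T_asym - t0) * exp(-t/tau)`` plus
    reading noise.  Cold conditions produce physiologically implausible
    readings (the sensor artefact) and are flagged ``valid=False``.
    """
    if any(m < 0 for m in minutes):
        raise ValueError("minutes must be non-negative")
    if asymptote is None:
        t_asym = TEMP_ASYMPTOTE.get(condition, TEMP_ASYMPTOTE["standard"])
    else:
        t_asym = asymptote
    readings = tuple(
        (float(m), float(t_asym - (t_asym - t0) * math.exp(-m / tau_min)
                         + rng.normal(0.0, noise_sd)))
        for m in minutes
    )
    return TemperatureSeries(
        dog=dog,
        condition=condition,
        readings=readings,
        valid=TEMP_VALID.get(condition, True),
    )


# ---------------------------------------------------------------------------
# experiment simulators


@dataclass
class SimulatedExperiment:
    """Everything one synthetic experiment produced."""

    thresholds: pd.DataFrame
    sessions: list[SessionResult]
    temperatures: list[TemperatureSeries]
    manifest: dict


def _covariates(session: SessionResult) -> tuple[Optional[float], Optional[float]]:
    """(mean searched-trial latency, mean per-trial IBI) from a trial log."""
    lats = [t.latency_s for t in session.trials if t.latency_s is not None]
    ibi_means = [
        float(np.mean(t.inter_box_intervals_s))
        for t in session.trials
        if t.inter_box_intervals_s
    ]
    mean_lat = float(np.mean(lats)) if lats else None
    mean_ibi = float(np.mean(ibi_means)) if ibi_means else None
    return mean_lat, mean_ibi


def _simulate_session(
    effects: EffectSpec,
    ladder: DilutionLadder,
    rules: TerminationRules,
    child_seed: np.random.SeedSequence,
    dog: str,
    breed: str,
    odor: str,
    condition: str,
    dog_effect: float,
    extra_shift: float = 0.0,
    group: str = "",
    day: Optional[int] = None,
    heat_index: Optional[float] = None,
    temp_asymptote: Optional[float] = None,
    p_no_search: Optional[float] = None,
) -> tuple[dict, SessionResult, TemperatureSeries]:
    rng = np.random.default_rng(child_seed)
    if heat_index is None:
        heat_index = HEAT_INDEX.get(condition, 0.0)
    if p_no_search is None:
        p_no_search = P_NO_SEARCH.get(condition, 0.0)

    # temperature trajectory first: the session lapse and any planted
    # temperature-mediated threshold shift condition on its 25-min mean
    temps = temp_trajectory(
        condition, minutes=np.arange(0.0, 41.0, 5.0), rng=rng, dog=dog,
        asymptote=temp_asymptote,
    )
    mean_temp = mean_session_temperature(temps)

    alpha = (
        effects.baseline_alpha[odor]
        + effects.shift(odor, condition)
        + dog_effect
        + extra_shift
        + rng.normal(0.0, effects.sigma_session)
    )
    if effects.temp_slope != 0.0 and mean_temp is not None:
        alpha += effects.temp_slope * (mean_temp - effects.temp_ref)

    observer = Observer(
        alpha=alpha,
        beta=effects.beta,
        lapse=effects.lapse_at(mean_temp),
        p_no_search=p_no_search,
    )
    deficit = alpha - effects.baseline_alpha[odor]
    timing = TimingModel(heat_index=heat_index)
    timing.mu_latency += effects.perf_timing_coef * max(0.0, deficit)
    timing.mu_ibi += effects.perf_timing_coef * max(0.0, deficit)

    session = run_session(
        observer,
        ladder,
        rules,
        rng,
        timing_model=timing,
        dog=dog,
        odor=odor,
        condition=condition,
        group=group,
        day=day,
    )
    record = session_threshold(session, rules, impute=True, breed=breed)
    record_np = session_threshold(session, rules, impute=False, breed=breed)
    mean_lat, mean_ibi = _covariates(session)
    row = {
        "dog": dog,
        "breed": breed,
        "group": group,
        "odor": odor,
        "condition": condition,
        "day": day,
        "log10_threshold": record.log10_threshold,
        "threshold_fraction": record.threshold_fraction,
        "log10_threshold_nonimputed": record_np.log10_threshold,
        "n_observed_reversals": record.n_observed_reversals,
        "imputation": record.imputation,
        "imputed_used": record.imputed_used,
        "termination_reason": session.termination_reason,
        "mean_temp_c": mean_temp,
        "mean_latency_s": mean_lat,
        "mean_ibi_s": mean_ibi,
        "true_alpha": alpha,
    }
    return row, session, temps


def simulate_experiment1(
    effects: Optional[EffectSpec] = None,
    design: Optional[DesignSpec] = None,
    seed: int = 0,
    ladder: Optional[DilutionLadder] = None,
    rules: Optional[TerminationRules] = None,
) -> SimulatedExperiment:
    """Simulate the crossed dogs x odors x conditions threshold experiment.

    Every dog runs one session per odor x condition (odors in the fixed
    testing order, conditions in the dog's counterbalanced order), giving
    ``n_dogs * n_odors * n_conditions`` sessions.  Deterministic given
    ``seed``.
    """
    effects = effects or EffectSpec()
    design = design or DesignSpec()
    ladder = ladder or default_ladder()
    rules = rules or TerminationRules(reversals_required=7)

    master = np.random.SeedSequence(seed)
    n_sessions = len(design.dogs) * len(design.odors) * len(design.conditions)
    children = iter(master.spawn(n_sessions + 1))
    dog_rng = np.random.default_rng(next(children))
    dog_effects = {
        d: float(dog_rng.normal(0.0, effects.sigma_dog)) for d in design.dogs
    }

    rows, sessions, temps = [], [], []
    for dog in design.dogs:
        grp = design.order_group_of(dog)
        for odor in ODOR_ORDER:
            if odor not in design.odors:
                continue
            order = CONDITION_ORDERS.get((grp, odor), design.conditions)
            for condition in order:
                if condition not in design.conditions:
                    continue
                row, sess, tseries = _simulate_session(
                    effects, ladder, rules, next(children),
                    dog=dog, breed=design.breed_of(dog),
                    odor=odor, condition=condition,
                    dog_effect=dog_effects[dog],
                )
                rows.append(row)
                sessions.append(sess)
                temps.append(tseries)

    manifest = {
        "experiment": 1,
        "seed": seed,
        "n_sessions": len(sessions),
        "baseline_alpha": dict(effects.baseline_alpha),
        "condition_shift": {f"{o}:{c}": v for (o, c), v in effects.condition_shift.items()},
        "sigma_dog": effects.sigma_dog,
        "sigma_session": effects.sigma_session,
        "beta": effects.beta,
        "temp_slope": effects.temp_slope,
        "dog_effects": dog_effects,
        "rules": {"reversals_required": rules.reversals_required},
    }
    return SimulatedExperiment(
        thresholds=pd.DataFrame(rows),
        sessions=sessions,
        temperatures=temps,
        manifest=manifest,
    )


def simulate_experiment2(
    effects: Optional[EffectSpec] = None,
    design: Optional[DesignSpec] = None,
    seed: int = 0,
    ladder: Optional[DilutionLadder] = None,
    rules: Optional[TerminationRules] = None,
    odor: str = "C4",
) -> SimulatedExperiment:
    """Simulate the 22-day two-group acclimatization study.

    Both groups run a daily 4-reversal session with the headline odorant.
    The acclimatization group's chamber ramps to the hot condition over six
    days; days 11 and 22 place both groups in the hot condition, where the
    planted ``group_effect`` (negative = acclimatized dogs detect better)
    separates the groups.  Training-day condition effects scale linearly
    with the chamber temperature between standard and hot setpoints.
    """
    effects = effects or EffectSpec()
    design = design or DesignSpec()
    ladder = ladder or default_ladder()
    rules = rules or TerminationRules(reversals_required=4)

    master = np.random.SeedSequence(seed)
    n_sessions = len(design.dogs) * len(design.exp2_days)
    children = iter(master.spawn(n_sessions + 1))
    dog_rng = np.random.default_rng(next(children))
    dog_effects = {
        d: float(dog_rng.normal(0.0, effects.sigma_dog)) for d in design.dogs
    }

    hot_shift = effects.shift(odor, "HTHH")
    t_std, t_hot = CONDITIONS["standard"][0], CONDITIONS["HTHH"][0]

    rows, sessions, temps = [], [], []
    for dog in design.dogs:
        grp = design.exp2_group_of(dog)
        for day in design.exp2_days:
            t_c, rh, label = exp2_setpoint(day, grp)
            # condition effect scales with chamber temperature along the ramp
            frac_hot = max(0.0, min(1.0, (t_c - t_std) / (t_hot - t_std)))
            extra = hot_shift * frac_hot - effects.shift(odor, label)
            if day in design.exp2_test_days and grp == "acclimatization":
                extra += effects.group_effect
            std_asym, hot_asym = TEMP_ASYMPTOTE["standard"], TEMP_ASYMPTOTE["HTHH"]
            row, sess, tseries = _simulate_session(
                effects, ladder, rules, next(children),
                dog=dog, breed=design.breed_of(dog),
                odor=odor, condition=label,
                dog_effect=dog_effects[dog],
                extra_shift=extra, group=grp, day=day,
                heat_index=HEAT_INDEX["HTHH"] * frac_hot,
                temp_asymptote=std_asym + (hot_asym - std_asym) * frac_hot,
                p_no_search=P_NO_SEARCH["HTHH"] * frac_hot,
            )
            row["is_test_day"] = day in design.exp2_test_days
            row["setpoint_temp_c"] = t_c
            row["setpoint_rh"] = rh
            rows.append(row)
            sessions.append(sess)
            temps.append(tseries)

    manifest = {
        "experiment": 2,
        "seed": seed,
        "odor": odor,
        "n_sessions": len(sessions),
        "group_effect": effects.group_effect,
        "hot_shift": hot_shift,
        "sigma_dog": effects.sigma_dog,
        "sigma_session": effects.sigma_session,
        "dog_effects": dog_effects,
        "rules": {"reversals_required": rules.reversals_required},
        "test_days": list(design.exp2_test_days),
    }
    return SimulatedExperiment(
        thresholds=pd.DataFrame(rows),
        sessions=sessions,
        temperatures=temps,
        manifest=manifest,
    )
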