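"""Behavioral and physiological covariates from event-level logs.

Three session covariates accompany each threshold: search latency (trial
start to first nose poke), the inter-box interval (nose-poke-to-nose-poke
travel time between *different* odor ports), and the mean subcutaneous
temperature over the first part of the session.  A nose poke is an infrared
beam break; dwell time (release - break) is retained in the event records but
unused by these metrics.  Missing covariates stay missing and propagate into
the regressions as complete-case deletion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "BeamEvent",
    "TemperatureSeries",
    "trial_latency",
    "inter_box_intervals",
    "session_mean_ibi",
    "mean_session_temperature",
]


@dataclass(frozen=True)
class BeamEvent:
    """One infrared-beam break at an odor port."""

    box: int  # port id, 1-3
    break_s: float  # seconds from session start
    release_s: float

    def __post_init__(self) -> None:
        if self.release_s < self.break_s:
            raise ValueError("release_s must be >= break_s")


@dataclass(frozen=True)
class TemperatureSeries:
    """Subcutaneous temperature readings for one session.

    ``readings`` are (minutes from session start, deg C) pairs, times
    non-decreasing.  ``valid=False`` marks series whose readings are
    physiologically implausible (cold-condition sensor artefacts) and
    excluded from analysis.
    """

    dog: str
    condition: str
    readings: tuple[tuple[float, float], ...]
    valid: bool = True

    def __post_init__(self) -> None:
        times = [t for t, _ in self.readings]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("reading times must be non-decreasing")


def trial_latency(
    trial_start_s: float, events: Sequence[BeamEvent]
) -> Optional[float]:
    """Seconds from trial start to the first nose poke at/after it.

    Returns None when no beam break occurs during the trial.
    """
    for ev in events:
        if ev.break_s >= trial_start_s:
            return ev.break_s - trial_start_s
    return None


def inter_box_intervals(events: Sequence[BeamEvent]) -> list[float]:
    """Break-time gaps between successive nose pokes at *different* boxes.

    Consecutive re-pokes of the same box are not travel and are excluded:
    the interval is measured from the last poke to the next poke at a new
    box.
    """
    intervals: list[float] = []
    prev: Optional[BeamEvent] = None
    for ev in events:
        if prev is not None and ev.box != prev.box:
            intervals.append(ev.break_s - prev.break_s)
        prev = ev
    return intervals


def session_mean_ibi(
    trial_events: Sequence[Sequence[BeamEvent]],
) -> Optional[float]:
    """Session mean inter-box interval, averaging within then across trials.

    Trials with fewer than two distinct-box pokes contribute nothing; returns
    None when no trial yields an interval.
    """
    trial_means = []
    for events in trial_events:
        ivals = inter_box_intervals(events)
        if ivals:
            trial_means.append(sum(ivals) / len(ivals))
    if not trial_means:
        return None
    return sum(trial_means) / len(trial_means)


def mean_session_temperature(
    series: TemperatureSeries, window_min: float = 25.0
) -> Optional[float]:
    """Arithmetic mean temperature over readings within the first ``window_min``.

    Returns None for invalid series (dropped sensor data) or when no reading
    falls inside the window.
    """
    if not series.valid:
        return None
    temps = [temp for t, temp in series.readings if t <= window_min]
    if not temps:
        return None
    return sum(temps) / len(temps)
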