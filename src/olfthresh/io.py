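"""Canonical CSV schemas, readers/writers, column mappings, run config.

The pipeline's canonical on-disk form is a pair of CSVs per experiment —
``sessions.csv`` (one row per session: identity, termination reason,
observed reversals) and ``trials.csv`` (one row per presented trial) — plus
``temperatures.csv``, ``thresholds.csv`` and ``voc.csv``.  All times are
seconds from session start, temperatures degC, concentrations unitless
fractions.  List-valued fields (reversals, inter-box intervals) are
semicolon-joined so a written session reads back identically.

Supplementary files with other column names attach through a
:class:`ColumnMapping` rather than hard-coded headers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from olfthresh.behavior_metrics import TemperatureSeries
from olfthresh.staircase import SessionResult, TrialRecord

__all__ = [
    "ColumnMapping",
    "RunConfig",
    "write_sessions",
    "read_sessions",
    "write_temperatures",
    "read_temperatures",
    "read_voc",
    "write_thresholds",
    "read_thresholds",
]

TRIAL_COLUMNS = [
    "session_id", "trial_index", "step", "fraction", "outcome",
    "latency_s", "inter_box_s", "t_start_s",
]
SESSION_COLUMNS = [
    "session_id", "dog", "breed", "group", "odor", "condition", "day",
    "termination_reason", "duration_min", "reversals",
]
TEMPERATURE_COLUMNS = ["session_id", "dog", "condition", "minute", "temp_c", "valid"]
VOC_COLUMNS = ["odor", "condition", "replicate", "total_voc_ppm"]

_OUTCOMES = {"correct", "incorrect", "no_search"}


@dataclass(frozen=True)
class ColumnMapping:
    """Native-to-canonical column renames, one dict per file kind."""

    trials: dict[str, str] = field(default_factory=dict)
    sessions: dict[str, str] = field(default_factory=dict)
    temperature: dict[str, str] = field(default_factory=dict)
    voc: dict[str, str] = field(default_factory=dict)

    def apply(self, df: pd.DataFrame, kind: str) -> pd.DataFrame:
        mapping = getattr(self, kind)
        out = df.rename(columns=mapping)
        required = {
            "trials": TRIAL_COLUMNS,
            "sessions": SESSION_COLUMNS,
            "temperature": TEMPERATURE_COLUMNS,
            "voc": VOC_COLUMNS,
        }[kind]
        missing = [c for c in required if c not in out.columns]
        if missing:
            raise ValueError(
                f"{kind} file is missing required columns {missing}; "
                "map them via ColumnMapping"
            )
        return out


def _join(values: Sequence[float]) -> str:
    return ";".join(repr(float(v)) for v in values)


def _split(text) -> tuple[float, ...]:
    if text is None or (isinstance(text, float) and pd.isna(text)) or text == "":
        return ()
    return tuple(float(v) for v in str(text).split(";"))


def session_id_of(session: SessionResult) -> str:
    parts = [session.dog, session.odor, session.condition]
    if session.day is not None:
        parts.append(f"d{session.day}")
    return "_".join(parts)


# ---------------------------------------------------------------------------
# sessions + trials


def write_sessions(
    sessions: Sequence[SessionResult],
    out_dir: str | Path,
    breeds: Optional[dict[str, str]] = None,
) -> tuple[Path, Path]:
    """Write sessions.csv and trials.csv; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    srows, trows = [], []
    for s in sessions:
        sid = session_id_of(s)
        srows.append(
            {
                "session_id": sid,
                "dog": s.dog,
                "breed": (breeds or {}).get(s.dog, ""),
                "group": s.group,
                "odor": s.odor,
                "condition": s.condition,
                "day": s.day if s.day is not None else "",
                "termination_reason": s.termination_reason,
                "duration_min": s.session_duration_min,
                "reversals": _join(s.observed_reversals),
            }
        )
        for t in s.trials:
            trows.append(
                {
                    "session_id": sid,
                    "trial_index": t.trial_index,
                    "step": t.presented_step,
                    "fraction": t.presented_fraction,
                    "outcome": t.outcome,
                    "latency_s": t.latency_s if t.latency_s is not None else "",
                    "inter_box_s": _join(t.inter_box_intervals_s),
                    "t_start_s": t.trial_start_s,
                }
            )
    spath, tpath = out_dir / "sessions.csv", out_dir / "trials.csv"
    pd.DataFrame(srows, columns=SESSION_COLUMNS).to_csv(spath, index=False)
    pd.DataFrame(trows, columns=TRIAL_COLUMNS).to_csv(tpath, index=False)
    return spath, tpath


def read_sessions(
    sessions_path: str | Path,
    trials_path: str | Path,
    mapping: Optional[ColumnMapping] = None,
) -> tuple[list[SessionResult], pd.DataFrame]:
    """Read session and trial CSVs back into typed sessions.

    Malformed trial rows (unknown outcome, unparseable numbers) are collected
    into the returned reject report instead of aborting the load.
    """
    mapping = mapping or ColumnMapping()
    sdf = mapping.apply(pd.read_csv(sessions_path, dtype={"day": "object"}, float_precision="round_trip"), "sessions")
    tdf = mapping.apply(pd.read_csv(trials_path, float_precision="round_trip"), "trials")

    rejects = []
    trials_by_sid: dict[str, list[TrialRecord]] = {}
    for i, row in tdf.iterrows():
        try:
            outcome = str(row["outcome"])
            if outcome not in _OUTCOMES:
                raise ValueError(f"unknown outcome {outcome!r}")
            lat = row["latency_s"]
            latency = None if pd.isna(lat) or lat == "" else float(lat)
            rec = TrialRecord(
                trial_index=int(row["trial_index"]),
                presented_step=int(row["step"]),
                presented_fraction=float(row["fraction"]),
                outcome=outcome,  # type: ignore[arg-type]
                latency_s=latency,
                inter_box_intervals_s=_split(row["inter_box_s"]),
                trial_start_s=float(row["t_start_s"]),
            )
        except (ValueError, TypeError) as exc:
            rejects.append({"row": int(i), "error": str(exc), **row.to_dict()})
            continue
        trials_by_sid.setdefault(str(row["session_id"]), []).append(rec)

    sessions = []
    for _, row in sdf.iterrows():
        day = row["day"]
        day_val = None if pd.isna(day) or day == "" else int(float(day))
        sid = str(row["session_id"])
        sessions.append(
            SessionResult(
                dog=str(row["dog"]),
                odor=str(row["odor"]),
                condition=str(row["condition"]),
                trials=tuple(sorted(trials_by_sid.get(sid, []),
                                    key=lambda t: t.trial_index)),
                observed_reversals=_split(row["reversals"]),
                termination_reason=str(row["termination_reason"]),  # type: ignore[arg-type]
                session_duration_min=float(row["duration_min"]),
                group="" if pd.isna(row["group"]) else str(row["group"]),
                day=day_val,
            )
        )
    return sessions, pd.DataFrame(rejects)


# ---------------------------------------------------------------------------
# temperatures, VOC, thresholds


def write_temperatures(
    series: Sequence[TemperatureSeries],
    path: str | Path,
    session_ids: Optional[Sequence[str]] = None,
) -> Path:
    rows = []
    for i, ts in enumerate(series):
        sid = session_ids[i] if session_ids is not None else f"{ts.dog}_{ts.condition}_{i}"
        for minute, temp in ts.readings:
            rows.append(
                {"session_id": sid, "dog": ts.dog, "condition": ts.condition,
                 "minute": minute, "temp_c": temp, "valid": ts.valid}
            )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=TEMPERATURE_COLUMNS).to_csv(path, index=False)
    return path


def read_temperatures(
    path: str | Path, mapping: Optional[ColumnMapping] = None
) -> list[TemperatureSeries]:
    mapping = mapping or ColumnMapping()
    df = mapping.apply(pd.read_csv(path, float_precision="round_trip"), "temperature")
    out = []
    for sid, sub in df.groupby("session_id", sort=False):
        sub = sub.sort_values("minute")
        out.append(
            TemperatureSeries(
                dog=str(sub["dog"].iloc[0]),
                condition=str(sub["condition"].iloc[0]),
                readings=tuple(
                    (float(m), float(t)) for m, t in zip(sub["minute"], sub["temp_c"])
                ),
                valid=bool(sub["valid"].iloc[0]),
            )
        )
    return out


def read_voc(path: str | Path, mapping: Optional[ColumnMapping] = None) -> pd.DataFrame:
    """VOC replicate table; warns (in the reject sense) via a 'complete' flag."""
    mapping = mapping or ColumnMapping()
    df = mapping.apply(pd.read_csv(path), "voc")
    if (df["total_voc_ppm"] < 0).any():
        raise ValueError("total_voc_ppm must be non-negative")
    return df


def write_thresholds(records: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, index=False)
    return path


def read_thresholds(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# run configuration


_CONFIG_DEFAULTS = {
    "experiment": 1,
    "seed": 0,
    "reversals_required": None,  # default 7 (exp 1) / 4 (exp 2)
    "floor_fraction": 0.03,
    "fail_fraction": 0.80,
    "time_cap_as_fail": True,
    "ladder": None,  # list of {step_number, odor_flow, clean_flow, nominal_fraction}
    "effects": {},  # EffectSpec overrides
    "column_mapping": {},
    "out_dir": "out",
}


@dataclass
class RunConfig:
    """Validated YAML-backed run configuration."""

    experiment: int = 1
    seed: int = 0
    reversals_required: Optional[int] = None
    floor_fraction: float = 0.03
    fail_fraction: float = 0.80
    time_cap_as_fail: bool = True
    ladder: Optional[list[dict]] = None
    effects: dict = field(default_factory=dict)
    column_mapping: dict = field(default_factory=dict)
    out_dir: str = "out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(_CONFIG_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = {**_CONFIG_DEFAULTS, **raw}
        cfg = cls(**merged)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")
        if not (0 < self.floor_fraction <= 1) or not (0 < self.fail_fraction <= 1):
            raise ValueError("imputation fractions must be in (0, 1]")
        if self.reversals_required is not None and self.reversals_required <= 0:
            raise ValueError("reversals_required must be positive")
        if self.ladder is not None:
            needed = {"step_number", "odor_flow", "clean_flow", "nominal_fraction"}
            for row in self.ladder:
                if not needed <= set(row):
                    raise ValueError(f"ladder rows need keys {sorted(needed)}")

    def effective_reversals(self) -> int:
        if self.reversals_required is not None:
            return self.reversals_required
        return 7 if self.experiment == 1 else 4

    def build_ladder(self):
        from olfthresh.olfactometer import DilutionLadder, DilutionStep, default_ladder

        if self.ladder is None:
            return default_ladder()
        return DilutionLadder(
            steps=tuple(
                DilutionStep(
                    step_number=int(r["step_number"]),
                    odor_flow=float(r["odor_flow"]),
                    clean_flow=float(r["clean_flow"]),
                    nominal_fraction=float(r["nominal_fraction"]),
                )
                for r in self.ladder
            )
        )

    def build_mapping(self) -> ColumnMapping:
        return ColumnMapping(**{k: dict(v) for k, v in self.column_mapping.items()})


def write_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
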