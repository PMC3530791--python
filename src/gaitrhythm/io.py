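"""Delimited-text readers/writers and pipeline configuration.

All tabular artifacts are comma-separated text with a header row. Traces
round-trip at full float precision (shortest-repr formatting). Hours of
day appear as 0-23 integers in files; human-readable reports additionally
carry the 4-digit clock style (``0800``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detect import (
    DEFAULT_BAND,
    DEFAULT_MAX_GAP,
    DEFAULT_MIN_CORRELATION,
    DEFAULT_REFRACTORY,
    DEFAULT_SAMPLE_INTERVAL,
    AccelTrace,
    StepSeries,
)
from .errors import TraceFormatError
from .hourly import HourlyProfile, HourRecord
from .norms import ControlNorms, Cutoffs
from .simulate import DiaryDay

TRACE_COLUMNS = ["time_s", "ax", "ay", "az"]
STEP_COLUMNS = ["time_s", "amplitude", "correlation"]
PROFILE_COLUMNS = ["hour", "n_steps", "cadence", "acceleration", "valid"]
DIARY_COLUMNS = ["hour", "state"]


def _read_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # header/tokenisation problems
        raise TraceFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TraceFormatError(
            f"{path}: missing expected columns {missing}; found {list(df.columns)}"
        )
    return df


def _require_numeric(df: pd.DataFrame, cols: list[str], path: Path) -> pd.DataFrame:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.index[coerced.isna() & df[c].notna()]
        if len(bad):
            # +2: header line and 1-based file numbering
            raise TraceFormatError(
                f"{path}: non-numeric value {df[c].iloc[bad[0]]!r} in column "
                f"{c!r} at line {bad[0] + 2}"
            )
        if coerced.isna().any():
            row = int(coerced.index[coerced.isna()][0])
            raise TraceFormatError(f"{path}: missing value in column {c!r} at line {row + 2}")
        df[c] = coerced
    return df


def read_trace(path: str | Path, sample_interval: float | None = None,
               start_hour: float = 0.0, subject_id: str = "") -> AccelTrace:
    path = Path(path)
    df = _require_numeric(_read_csv(path, TRACE_COLUMNS), TRACE_COLUMNS, path)
    t = df["time_s"].to_numpy()
    if sample_interval is None:
        sample_interval = float(np.median(np.diff(t))) if t.size > 1 else DEFAULT_SAMPLE_INTERVAL
    return AccelTrace(
        samples=df[["ax", "ay", "az"]].to_numpy(),
        sample_interval=sample_interval,
        start_hour=start_hour,
        subject_id=subject_id or path.stem,
    )


def write_trace(trace: AccelTrace, path: str | Path) -> None:
    df = pd.DataFrame(trace.samples, columns=["ax", "ay", "az"])
    df.insert(0, "time_s", trace.times)
    df.to_csv(path, index=False)


def read_steps(path: str | Path, start_hour: float = 0.0) -> StepSeries:
    path = Path(path)
    df = _require_numeric(_read_csv(path, STEP_COLUMNS), STEP_COLUMNS, path)
    return StepSeries(
        times=df["time_s"].to_numpy(),
        amplitudes=df["amplitude"].to_numpy(),
        correlations=df["correlation"].to_numpy(),
        trace_start_hour=start_hour,
        subject_id=path.stem,
    )


def write_steps(series: StepSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": series.times, "amplitude": series.amplitudes,
         "correlation": series.correlations}
    ).to_csv(path, index=False)


def read_profile(path: str | Path) -> HourlyProfile:
    path = Path(path)
    df = _read_csv(path, PROFILE_COLUMNS)
    hours = []
    for _, row in df.iterrows():
        valid = bool(row["valid"])
        hours.append(
            HourRecord(
                hour=int(row["hour"]),
                n_steps=int(row["n_steps"]),
                cadence=float(row["cadence"]) if valid else None,
                acceleration=float(row["acceleration"]) if valid else None,
                valid=valid,
            )
        )
    return HourlyProfile(hours=hours, subject_id=path.stem)


def write_profile(profile: HourlyProfile, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "hour": h.hour,
                "n_steps": h.n_steps,
                "cadence": h.cadence if h.valid else "",
                "acceleration": h.acceleration if h.valid else "",
                "valid": h.valid,
            }
            for h in profile.hours
        ]
    ).to_csv(path, index=False)


def read_diary(path: str | Path) -> DiaryDay:
    path = Path(path)
    df = _read_csv(path, DIARY_COLUMNS)
    states = {}
    for i, row in df.iterrows():
        states[int(row["hour"])] = str(row["state"]).strip()
    return DiaryDay(states=states, subject_id=path.stem)


def write_diary(diary: DiaryDay, path: str | Path) -> None:
    pd.DataFrame(
        sorted(diary.states.items()), columns=DIARY_COLUMNS
    ).to_csv(path, index=False)


def write_norms(norms: ControlNorms, cutoffs: Cutoffs, path: str | Path) -> None:
    doc = {"norms": dataclasses.asdict(norms), "cutoffs": dataclasses.asdict(cutoffs)}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_norms(path: str | Path) -> tuple[ControlNorms, Cutoffs]:
    doc = yaml.safe_load(Path(path).read_text())
    return ControlNorms(**doc["norms"]), Cutoffs(**doc["cutoffs"])


def clock_style(hour: int) -> str:
    """0-23 integer hour in 4-digit clock style (8 → '0800')."""
    return f"{hour:02d}00"


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters; round-trips losslessly through YAML."""

    sample_interval: float = DEFAULT_SAMPLE_INTERVAL
    min_correlation: float = DEFAULT_MIN_CORRELATION
    refractory: float = DEFAULT_REFRACTORY
    band: tuple[float, float] = DEFAULT_BAND
    max_gap: float = DEFAULT_MAX_GAP
    cutoff_source: str = "reference"  # 'reference' (published norms) | 'computed'
    cv_ddof: int = 0  # population CV by default
    sync_tolerance: int = 0  # hours; 0 = exact shared clock hour
    awareness: float = 1.0
    n_patients: int = 5
    n_controls: int = 5
    n_hours: int = 24
    walking_minutes: float = 10.0
    seed: int = 0
    out_dir: str = "pipeline_out"

    def __post_init__(self) -> None:
        if self.cutoff_source not in ("reference", "computed"):
            raise TraceFormatError(
                f"cutoff_source must be 'reference' or 'computed'; "
                f"got {self.cutoff_source!r}"
            )
        self.band = tuple(self.band)  # type: ignore[assignment]

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
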