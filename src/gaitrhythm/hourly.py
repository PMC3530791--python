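"""Hourly aggregation of detected steps into cadence and acceleration.

Cadence and gait acceleration are summarised per clock hour as means of the
per-step quantities. Hours with fewer than 20 detected steps carry too
little gait to estimate either and are flagged invalid; they are excluded
from every downstream statistic. Cadence is a rhythm (60 / mean step
interval), not an activity count, so a subject who walks only ten minutes
of an hour still reads at their true cadence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import DEFAULT_MAX_GAP, StepSeries
from .errors import InsufficientDataError, InvalidParameterError

MIN_STEPS_PER_HOUR = 20


@dataclass
class HourRecord:
    hour: int  # 0-23, clock-aligned
    n_steps: int
    cadence: float | None  # steps/min; None when invalid
    acceleration: float | None  # m/s² mean step amplitude; None when invalid
    valid: bool


@dataclass
class HourlyProfile:
    """Per clock-hour mean cadence and mean gait acceleration."""

    hours: list[HourRecord]
    subject_id: str = ""

    def valid_hours(self) -> list[HourRecord]:
        return [h for h in self.hours if h.valid]

    @property
    def n_valid(self) -> int:
        return len(self.valid_hours())

    def cadences(self) -> np.ndarray:
        return np.array([h.cadence for h in self.valid_hours()], dtype=float)

    def accelerations(self) -> np.ndarray:
        return np.array([h.acceleration for h in self.valid_hours()], dtype=float)


@dataclass
class AccelCV:
    """Coefficient of variation of the valid hourly accelerations."""

    cv: float
    n_hours: int


def build_profile(
    series: StepSeries,
    start_hour: float | None = None,
    max_gap: float = DEFAULT_MAX_GAP,
) -> HourlyProfile:
    """Bin step events by wall-clock hour and summarise each hour.

    Per valid hour (>= 20 steps): cadence = 60 / mean inter-event interval
    with both endpoints inside the hour and gaps > ``max_gap`` excluded as
    bout boundaries; acceleration = mean event amplitude. Recordings must
    not exceed 24 h (hour-of-day keys would collide).
    """
    if start_hour is None:
        start_hour = series.trace_start_hour
    if not 0 <= start_hour < 24:
        raise InvalidParameterError(f"start_hour must be in [0, 24); got {start_hour}")
    t = series.times
    if t.size and t[-1] > 24 * 3600:
        raise InvalidParameterError("recording longer than 24 h is not supported")

    abs_hour = (start_hour + t / 3600.0).astype(int)  # hours since day start
    records: list[HourRecord] = []
    present = np.unique(abs_hour) if t.size else np.array([], dtype=int)
    n_hours_total = int(np.ceil(start_hour + (t[-1] / 3600.0 if t.size else 0))) or 1
    for h in range(int(start_hour), max(n_hours_total, int(start_hour) + 1)):
        in_hour = abs_hour == h
        n = int(in_hour.sum())
        hour_of_day = h % 24
        if n < MIN_STEPS_PER_HOUR:
            records.append(HourRecord(hour_of_day, n, None, None, False))
            continue
        times_h = t[in_hour]
        iv = np.diff(times_h)
        iv = iv[iv <= max_gap]
        if iv.size == 0:
            # >= 20 events but no usable rhythm (all gaps): unmeasurable hour
            records.append(HourRecord(hour_of_day, n, None, None, False))
            continue
        cadence = 60.0 / float(iv.mean())
        accel = float(series.amplitudes[in_hour].mean())
        records.append(HourRecord(hour_of_day, n, cadence, accel, True))
    del present
    return HourlyProfile(hours=records, subject_id=series.subject_id)


def acceleration_cv(profile: HourlyProfile, ddof: int = 0) -> AccelCV:
    """SD / mean of the valid hourly accelerations (population SD by default)."""
    acc = profile.accelerations()
    if acc.size < 2:
        raise InsufficientDataError(
            f"acceleration CV needs >= 2 valid hours; got {acc.size}"
        )
    mean = float(acc.mean())
    if mean <= 0:
        raise InvalidParameterError("mean hourly acceleration must be positive")
    return AccelCV(cv=float(acc.std(ddof=ddof)) / mean, n_hours=int(acc.size))
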