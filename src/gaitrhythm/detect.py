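"""Gait step detection from tri-axial trunk acceleration.

The device records ax, ay, az at a fixed sampling interval (10 ms by
default). Gait leaves a stereotyped, roughly periodic pulse in the
acceleration-magnitude signal a = sqrt(ax^2 + ay^2 + az^2), one pulse per
step. Detection proceeds in two stages:

1. ``extract_template`` — recover the subject's own step pulse shape by
   band-passing the magnitude signal, picking prominent peaks, selecting the
   most rhythmically regular contiguous run of peaks, and averaging
   fixed-length windows centred on them.
2. ``match_steps`` — slide a Pearson correlation of the magnitude signal
   against the template; local correlation maxima above a threshold, thinned
   by a refractory interval, are accepted as steps. This pattern-matching
   step is what separates gait pulses from other limb/trunk movements and
   one-off artifacts, which correlate poorly with the template.

One accepted match is one step, so cadence (steps/min) is 60 divided by the
mean inter-event interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import InvalidParameterError, NoTemplateError

DEFAULT_SAMPLE_INTERVAL = 0.01  # s
DEFAULT_BAND = (0.5, 5.0)  # Hz; brackets pathological cadences on both sides
DEFAULT_TEMPLATE_DURATION = 0.6  # s
DEFAULT_MIN_CORRELATION = 0.6
DEFAULT_REFRACTORY = 0.25  # s; shortest credible step spacing (240 steps/min)
DEFAULT_MAX_GAP = 2.0  # s; longer inter-event gaps are bout boundaries


@dataclass
class AccelTrace:
    """Uniformly sampled tri-axial acceleration record.

    Parameters
    ----------
    samples : (n, 3) float array
        Acceleration along x, y, z in m/s².
    sample_interval : float
        Seconds between samples (default 0.01).
    start_hour : float
        Wall-clock hour of day at the first sample (0–24).
    subject_id : str
        Free-form identifier carried through to reports.
    """

    samples: np.ndarray
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL
    start_hour: float = 0.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise InvalidParameterError(
                f"samples must be (n, 3); got shape {self.samples.shape}"
            )
        if not self.sample_interval > 0:
            raise InvalidParameterError(
                f"sample_interval must be > 0; got {self.sample_interval}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples * self.sample_interval

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sample_interval


@dataclass
class StepTemplate:
    """A single-step acceleration-magnitude pulse used for pattern matching."""

    waveform: np.ndarray
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.size == 0:
            raise InvalidParameterError("template waveform is empty")
        if not np.max(self.waveform) > 0:
            raise InvalidParameterError("template peak must be positive")

    @property
    def duration(self) -> float:
        return self.waveform.size * self.sample_interval

    @property
    def peak_offset(self) -> int:
        """Sample offset of the template peak from the window start."""
        return int(np.argmax(self.waveform))


@dataclass
class StepSeries:
    """Accepted gait events: times, peak magnitudes, match correlations."""

    times: np.ndarray  # s from trace start, strictly increasing
    amplitudes: np.ndarray  # m/s², magnitude at each matched wave's peak
    correlations: np.ndarray  # Pearson r of the matched window, in [-1, 1]
    trace_start_hour: float = 0.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.correlations = np.asarray(self.correlations, dtype=float)
        if not (self.times.shape == self.amplitudes.shape == self.correlations.shape):
            raise InvalidParameterError("event arrays must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("event times must be strictly increasing")

    @property
    def n_events(self) -> int:
        return self.times.size


def magnitude(trace: AccelTrace) -> np.ndarray:
    """Per-sample acceleration-vector magnitude a = sqrt(ax² + ay² + az²)."""
    s = trace.samples
    finite = np.isfinite(s).all(axis=1)
    if not finite.all():
        bad = int(np.argmin(finite))
        raise InvalidParameterError(f"non-finite acceleration at sample index {bad}")
    ax, ay, az = s[:, 0], s[:, 1], s[:, 2]
    return np.sqrt(ax * ax + ay * ay + az * az)


def extract_template(
    trace: AccelTrace,
    band: tuple[float, float] = DEFAULT_BAND,
    template_duration: float = DEFAULT_TEMPLATE_DURATION,
    max_windows: int = 30,
    min_peaks: int = 8,
    max_interval_cv: float = 0.15,
) -> StepTemplate:
    """Build a subject-specific step template from a walking trace.

    Band-passes the magnitude signal, picks peaks at least one refractory
    interval apart, selects the contiguous run of up to ``max_windows`` peaks
    whose inter-peak intervals are most regular (lowest coefficient of
    variation), and averages raw-magnitude windows of ``template_duration``
    centred on those peaks. Raises :class:`NoTemplateError` when no
    sufficiently regular run exists (e.g. a trace without walking).
    """
    a = magnitude(trace)
    dt = trace.sample_interval
    fs = 1.0 / dt
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise InvalidParameterError(f"band {band} invalid for fs={fs:g} Hz")
    sos = sps.butter(2, (lo, hi), btype="bandpass", fs=fs, output="sos")
    f = sps.sosfiltfilt(sos, a)

    distance = max(1, int(round(DEFAULT_REFRACTORY / dt)))
    peaks, props = sps.find_peaks(f, distance=distance, prominence=1e-9)
    if peaks.size >= min_peaks:
        # drop filter-ripple micro-peaks: keep peaks within reach of the
        # prominent ones (gait pulses dwarf ripple by orders of magnitude)
        floor = 0.25 * np.quantile(props["prominences"], 0.95)
        peaks = peaks[props["prominences"] >= floor]
    if peaks.size < min_peaks:
        raise NoTemplateError(
            f"only {peaks.size} candidate peaks; need >= {min_peaks}"
        )

    intervals = np.diff(peaks).astype(float)
    run_len = min(max_windows, peaks.size)
    n_iv = run_len - 1
    # Score every contiguous run of run_len peaks by interval regularity
    # (CV of the run's inter-peak intervals), via rolling sums.
    c1 = np.concatenate(([0.0], np.cumsum(intervals)))
    c2 = np.concatenate(([0.0], np.cumsum(intervals * intervals)))
    s1 = c1[n_iv:] - c1[:-n_iv]
    s2 = c2[n_iv:] - c2[:-n_iv]
    mean = s1 / n_iv
    var = np.clip(s2 / n_iv - mean * mean, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        cvs = np.where(mean > 0, np.sqrt(var) / mean, np.inf)
    start = int(np.argmin(cvs))
    best_cv = float(cvs[start])
    best_run = peaks[start : start + run_len]
    if not np.isfinite(best_cv) or best_cv > max_interval_cv:
        raise NoTemplateError(
            f"no periodic run found (best interval CV {best_cv:.3f} "
            f"> {max_interval_cv})"
        )

    half = int(round(template_duration / dt)) // 2
    windows = [
        a[p - half : p + half]
        for p in best_run
        if p - half >= 0 and p + half <= a.size
    ]
    if len(windows) < min_peaks:
        raise NoTemplateError("too few full windows around the periodic run")
    return StepTemplate(np.mean(windows, axis=0), sample_interval=dt)


#: MAD about the median of |N(0, I_3)| (chi distribution, 3 df); converts a
#: robust spread of noise-only magnitude samples into the per-axis noise SD.
_CHI3_MAD = 0.46024377


def _sliding_pearson(a: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Pearson correlation of every length-len(t) window of ``a`` with ``t``."""
    m = t.size
    t_c = t - t.mean()
    sst = float(np.dot(t_c, t_c))
    if sst <= 0:
        raise InvalidParameterError("template is constant; correlation undefined")
    cross = sps.oaconvolve(a, t_c[::-1], mode="valid")
    c = np.concatenate(([0.0], np.cumsum(a)))
    c2 = np.concatenate(([0.0], np.cumsum(a * a)))
    s1 = c[m:] - c[:-m]
    s2 = c2[m:] - c2[:-m]
    var_w = s2 - s1 * s1 / m  # m * window variance
    denom = np.sqrt(np.clip(var_w, 0.0, None) * sst)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 1e-12, cross / denom, 0.0)
    return np.clip(r, -1.0, 1.0)


def _noise_sd_from_gaps(a: np.ndarray, lags: np.ndarray, m: int,
                        min_gap_samples: int = 1000) -> float:
    """Per-axis sensor noise SD from samples outside every matched window.

    Those samples carry only the magnitude of the tri-axial noise vector
    (a chi-distributed floor), whose robust spread converts to the axis SD.
    Returns 0 when too few gap samples exist (e.g. wall-to-wall gait, or a
    noiseless trace whose gaps are exactly zero yield 0 as well).
    """
    covered = np.zeros(a.size, dtype=bool)
    for lag in lags:
        covered[lag : lag + m] = True
    gap = a[~covered]
    if gap.size < min_gap_samples:
        return 0.0
    mad = float(np.median(np.abs(gap - np.median(gap))))
    return mad / _CHI3_MAD


def match_steps(
    trace: AccelTrace,
    template: StepTemplate,
    min_correlation: float = DEFAULT_MIN_CORRELATION,
    refractory: float = DEFAULT_REFRACTORY,
) -> StepSeries:
    """Detect gait steps by template correlation on the magnitude signal.

    Local correlation maxima >= ``min_correlation`` are accepted greedily,
    highest correlation first, subject to the ``refractory`` spacing. Each
    event is timed at the matched wave's peak sample and records the peak
    magnitude there as its amplitude, after removing the sensor noise
    floor: noise perpendicular to the gait pulse adds in quadrature, so the
    measured peak is deflated by ``sqrt(peak^2 - 2 sigma^2)`` with the
    per-axis ``sigma`` estimated from pulse-free stretches of the trace.
    """
    if not 0 < min_correlation < 1:
        raise InvalidParameterError(
            f"min_correlation must be in (0, 1); got {min_correlation}"
        )
    if not refractory > 0:
        raise InvalidParameterError(f"refractory must be > 0; got {refractory}")
    a = magnitude(trace)
    t = template.waveform
    if t.size > a.size:
        raise InvalidParameterError(
            f"template ({t.size} samples) longer than trace ({a.size})"
        )
    r = _sliding_pearson(a, t)

    dt = trace.sample_interval
    distance = max(1, int(round(refractory / dt)))
    # Pad so maxima at the lag-range boundaries are eligible.
    padded = np.concatenate(([-2.0], r, [-2.0]))
    lags, _ = sps.find_peaks(padded, height=min_correlation, distance=distance)
    lags -= 1

    peak_idx = lags + template.peak_offset
    peak_idx = np.clip(peak_idx, 0, a.size - 1)
    order = np.argsort(peak_idx)
    peak_idx, lags = peak_idx[order], lags[order]
    # Peak-offset shifts can only collide for adjacent lags closer than the
    # refractory spacing, which find_peaks already excludes; dedupe defensively.
    keep = np.concatenate(([True], np.diff(peak_idx) > 0))
    peak_idx, lags = peak_idx[keep], lags[keep]

    sigma = _noise_sd_from_gaps(a, lags, t.size)
    amplitudes = np.sqrt(np.clip(a[peak_idx] ** 2 - 2.0 * sigma**2, 0.0, None))
    return StepSeries(
        times=peak_idx * dt,
        amplitudes=amplitudes,
        correlations=r[lags],
        trace_start_hour=trace.start_hour,
        subject_id=trace.subject_id,
    )


def step_intervals(series: StepSeries, max_gap: float = DEFAULT_MAX_GAP) -> np.ndarray:
    """Consecutive inter-event intervals, dropping gaps longer than ``max_gap``.

    A gap above ``max_gap`` separates walking bouts and is not a step
    interval. Empty input yields an empty array.
    """
    if series.n_events < 2:
        return np.empty(0)
    iv = np.diff(series.times)
    return iv[iv <= max_gap]
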