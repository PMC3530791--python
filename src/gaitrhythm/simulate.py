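"""Synthetic 24-h accelerometer recordings with known ground truth.

The generator emulates the statistical structure the fluctuation rules
assume, not biomechanics: walking hours contain a train of stereotyped
single-step magnitude pulses (half-sine burst with an exponential-decay
tail) at a planted cadence with mildly jittered spacing, projected onto a
fixed unit direction across the three axes; per-axis Gaussian sensor noise
and occasional non-periodic artifact bursts are superimposed. Hours can be
planted as normal gait, bradykinetic off (low cadence, low amplitude),
short-stepping/festinating off (high cadence, low amplitude),
activity-related (high cadence, high amplitude), or rest.

Everything is driven by an explicit integer seed; a fixed plan and seed
reproduce the recording byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .detect import DEFAULT_SAMPLE_INTERVAL, AccelTrace
from .errors import InvalidParameterError
from .norms import REFERENCE_CUTOFFS, Cutoffs

SEGMENT_LABELS = ("normal", "off_bradykinetic", "off_shortstep", "activity", "rest")
OFF_SEGMENTS = ("off_bradykinetic", "off_shortstep")

DEFAULT_STEP_DURATION = 0.3  # s
DEFAULT_NOISE_SD = 0.2  # m/s² per axis
DEFAULT_ARTIFACT_RATE = 5.0  # bursts/hour
DEFAULT_JITTER_CV = 0.03  # multiplicative step-interval jitter
#: Fixed unit direction distributing the pulse over the axes; the analysis
#: only ever sees the magnitude, so the direction is a free choice.
PULSE_DIRECTION = np.array([1.0, 2.0, 2.0]) / 3.0


@dataclass
class HourPlan:
    """Planted gait content of one clock hour."""

    walking_minutes: float
    cadence: float  # steps/min
    step_amplitude: float  # m/s², pulse peak
    segment_label: str = "normal"


@dataclass
class DailyPlan:
    """Full specification of one simulated recording day."""

    hours: list[HourPlan]
    seed: int
    noise_sd: float = DEFAULT_NOISE_SD
    artifact_rate: float = DEFAULT_ARTIFACT_RATE
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL
    step_duration: float = DEFAULT_STEP_DURATION
    jitter_cv: float = DEFAULT_JITTER_CV
    start_hour: int = 0
    subject_id: str = ""

    def validate(self, cutoffs: Cutoffs = REFERENCE_CUTOFFS) -> None:
        """Check plan invariants, including label/geometry consistency.

        Planted off and activity hours must sit in the decision region their
        label names (relative to ``cutoffs``), so that recovery of the
        planted labels is well-posed.
        """
        if not self.hours:
            raise InvalidParameterError("plan has no hours")
        if len(self.hours) + self.start_hour > 24:
            raise InvalidParameterError("plan extends past 24 h")
        if self.noise_sd < 0 or self.artifact_rate < 0:
            raise InvalidParameterError("noise_sd and artifact_rate must be >= 0")
        for i, h in enumerate(self.hours):
            if h.segment_label not in SEGMENT_LABELS:
                raise InvalidParameterError(
                    f"hour {i}: unknown segment label {h.segment_label!r}"
                )
            if not 0 <= h.walking_minutes <= 60:
                raise InvalidParameterError(
                    f"hour {i}: walking_minutes {h.walking_minutes} outside [0, 60]"
                )
            if (h.walking_minutes == 0) != (h.segment_label == "rest"):
                raise InvalidParameterError(
                    f"hour {i}: walking_minutes == 0 iff segment_label == 'rest'"
                )
            if h.segment_label == "rest":
                continue
            if h.cadence <= 0 or h.step_amplitude <= 0:
                raise InvalidParameterError(
                    f"hour {i}: cadence and step_amplitude must be positive"
                )
            lbl = h.segment_label
            if lbl == "off_bradykinetic" and not (
                h.cadence < cutoffs.cadence_lo and h.step_amplitude < cutoffs.accel_off
            ):
                raise InvalidParameterError(
                    f"hour {i}: bradykinetic off needs cadence < {cutoffs.cadence_lo} "
                    f"and amplitude < {cutoffs.accel_off}"
                )
            if lbl == "off_shortstep" and not (
                h.cadence > cutoffs.cadence_hi and h.step_amplitude < cutoffs.accel_off
            ):
                raise InvalidParameterError(
                    f"hour {i}: short-step off needs cadence > {cutoffs.cadence_hi} "
                    f"and amplitude < {cutoffs.accel_off}"
                )
            if lbl == "activity" and not (
                h.cadence > cutoffs.cadence_hi and h.step_amplitude >= cutoffs.accel_off
            ):
                raise InvalidParameterError(
                    f"hour {i}: activity needs cadence > {cutoffs.cadence_hi} "
                    f"and amplitude >= {cutoffs.accel_off}"
                )


@dataclass
class GroundTruth:
    """Per-hour planted truth for one simulated subject."""

    hours: list[int]  # hour of day, 0-23
    labels: list[str]
    cadences: list[float]  # nan for rest hours
    amplitudes: list[float]  # nan for rest hours
    diary_states: list[str]  # 'good' / 'not_good' / 'bad'
    step_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    subject_id: str = ""

    def off_hours(self) -> set[int]:
        return {h for h, l in zip(self.hours, self.labels) if l in OFF_SEGMENTS}


def canonical_template(
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL,
    window: float = 0.6,
    step_duration: float = DEFAULT_STEP_DURATION,
):
    """Fallback matching template: the canonical step pulse centred in a
    full template-length window.

    Used when a trace is too sparse to self-template. The quiet shoulders
    around the pulse matter: they make the window long enough that random
    noise rarely reaches the acceptance correlation.
    """
    from .detect import StepTemplate  # local import; detect must not import us

    pulse = synth_step_waveform(1.0, step_duration, sample_interval)
    n = max(pulse.size, int(round(window / sample_interval)))
    wave = np.zeros(n)
    start = (n - pulse.size) // 2
    wave[start : start + pulse.size] = pulse
    return StepTemplate(wave, sample_interval=sample_interval)


def synth_step_waveform(
    step_amplitude: float,
    step_duration: float = DEFAULT_STEP_DURATION,
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL,
) -> np.ndarray:
    """Single-step magnitude pulse: half-sine burst shaped by an exponential
    decay tail, rescaled so the peak equals ``step_amplitude`` exactly.
    """
    if step_amplitude <= 0:
        raise InvalidParameterError(f"step_amplitude must be > 0; got {step_amplitude}")
    if step_duration <= 0 or sample_interval <= 0:
        raise InvalidParameterError("step_duration and sample_interval must be > 0")
    n = max(1, int(round(step_duration / sample_interval)))
    t = np.arange(n) * sample_interval
    raw = np.sin(np.pi * t / step_duration) * np.exp(-2.0 * t / step_duration)
    peak = raw.max()
    if peak <= 0:  # single-sample degenerate pulse
        raw = np.ones(n)
        peak = 1.0
    return step_amplitude * raw / peak


def _hour_step_times(hp: HourPlan, jitter_cv: float, rng: np.random.Generator) -> np.ndarray:
    """Step times (s from hour start) for one walking hour.

    Exactly round(cadence × walking_minutes) steps are placed in a single
    bout; jittered intervals are rescaled so their sum matches the bout
    length, keeping the planted cadence and step count exact on average.
    """
    n_steps = int(round(hp.cadence * hp.walking_minutes))
    if n_steps < 2:
        return np.empty(0)
    base = 60.0 / hp.cadence
    iv = base * np.clip(rng.normal(1.0, jitter_cv, n_steps - 1), 0.5, 1.5)
    bout = base * (n_steps - 1)
    slack = 3600.0 - bout - 2.0  # keep pulses clear of the hour edges
    if slack <= 0:
        # fully walked hour at low cadence: squeeze the bout inside the
        # hour (cadence error <= 0.1%)
        bout = 3599.0
        slack = 0.0
    iv *= bout / iv.sum()
    offset = 0.5 + (rng.uniform(0.0, slack) if slack > 0 else 0.0)
    return offset + np.concatenate(([0.0], np.cumsum(iv)))


def generate_trace(plan: DailyPlan) -> tuple[AccelTrace, GroundTruth]:
    """Render a plan into a tri-axial trace plus its ground truth."""
    plan.validate()
    rng = np.random.default_rng(plan.seed)
    dt = plan.sample_interval
    n_hours = len(plan.hours)
    samples_per_hour = int(round(3600.0 / dt))
    n = n_hours * samples_per_hour

    mag = np.zeros(n)
    truth_hours, labels, cadences, amps, diary = [], [], [], [], []
    all_steps = []
    for i, hp in enumerate(plan.hours):
        hour_of_day = (plan.start_hour + i) % 24
        truth_hours.append(hour_of_day)
        labels.append(hp.segment_label)
        is_rest = hp.segment_label == "rest"
        cadences.append(float("nan") if is_rest else hp.cadence)
        amps.append(float("nan") if is_rest else hp.step_amplitude)
        diary.append("bad" if hp.segment_label in OFF_SEGMENTS else "good")
        if is_rest:
            continue
        pulse = synth_step_waveform(hp.step_amplitude, plan.step_duration, dt)
        times = _hour_step_times(hp, plan.jitter_cv, rng)
        idx = np.round(times / dt).astype(int) + i * samples_per_hour
        idx = idx[idx + pulse.size <= n]  # every pulse fully inside the trace
        for j in idx:
            mag[j : j + pulse.size] += pulse
        # truth step times point at the pulse peak, matching detection's
        # event-time convention
        all_steps.append((idx + int(np.argmax(pulse))) * dt)

    axes = np.outer(mag, PULSE_DIRECTION)

    # Non-periodic artifact bursts: white-noise packets with a random
    # per-axis direction, dissimilar in shape to the step pulse.
    n_art = rng.poisson(plan.artifact_rate * n_hours)
    for _ in range(n_art):
        start = rng.integers(0, n)
        m = int(rng.uniform(0.1, 0.4) / dt)
        stop = min(start + m, n)
        burst = rng.normal(0.0, 1.5, (stop - start, 3))
        axes[start:stop] += burst

    if plan.noise_sd > 0:
        axes = axes + rng.normal(0.0, plan.noise_sd, (n, 3))

    trace = AccelTrace(
        samples=axes,
        sample_interval=dt,
        start_hour=float(plan.start_hour),
        subject_id=plan.subject_id,
    )
    truth = GroundTruth(
        hours=truth_hours,
        labels=labels,
        cadences=cadences,
        amplitudes=amps,
        diary_states=diary,
        step_times=np.sort(np.concatenate(all_steps)) if all_steps else np.empty(0),
        subject_id=plan.subject_id,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass
class OffSchedule:
    """Distributional parameters for planting off hours in patients.

    Ranges keep every planted hour strictly inside its decision region with
    margin to spare, so label recovery on the synthetic cohort is well-posed
    even after detection noise.
    """

    min_off_hours: int = 1
    max_off_hours: int = 4
    p_shortstep: float = 0.4  # vs bradykinetic
    brady_cadence: tuple[float, float] = (75.0, 90.0)
    shortstep_cadence: tuple[float, float] = (128.0, 145.0)
    off_amplitude: tuple[float, float] = (1.0, 1.5)
    p_activity_hour: float = 0.1
    activity_cadence: tuple[float, float] = (126.0, 140.0)
    activity_amplitude: tuple[float, float] = (3.2, 4.0)


@dataclass
class DiaryDay:
    """Hourly subjective diary; missing hours allowed."""

    states: dict[int, str]  # hour (0-23) -> 'good' | 'not_good' | 'bad'
    subject_id: str = ""


@dataclass
class SubjectRecord:
    subject_id: str
    kind: str  # 'patient' | 'control'
    trace: AccelTrace
    truth: GroundTruth
    diary: DiaryDay
    plan: DailyPlan


def _control_plan(rng: np.random.Generator, seed: int, subject_id: str,
                  walking_minutes: float, hourly_amp_cv: float,
                  hourly_cadence_sd: float) -> DailyPlan:
    # Control cohort geometry: subject-level cadence ~ N(110, 12) truncated
    # positive, gait acceleration ~ N(2.78, 0.42); hour-to-hour scatter sits
    # on top and drives the subject's day-long acceleration CV.
    cadence = float(np.clip(rng.normal(110.0, 12.0), 70.0, 160.0))
    amp = float(np.clip(rng.normal(2.78, 0.42), 1.2, None))
    hours = []
    for h in range(24):
        if 8 <= h <= 21:
            c = float(np.clip(rng.normal(cadence, hourly_cadence_sd), 60.0, 180.0))
            a = float(max(0.5, amp * (1.0 + rng.normal(0.0, hourly_amp_cv))))
            hours.append(HourPlan(walking_minutes, c, a, "normal"))
        else:
            hours.append(HourPlan(0.0, 0.0, 0.0, "rest"))
    return DailyPlan(hours=hours, seed=seed, subject_id=subject_id)


def _patient_plan(rng: np.random.Generator, seed: int, subject_id: str,
                  sched: OffSchedule, walking_minutes: float,
                  normal_amp_cv: float) -> DailyPlan:
    day_hours = list(range(7, 22))
    n_off = int(rng.integers(sched.min_off_hours, sched.max_off_hours + 1))
    off_hours = set(rng.choice(day_hours, size=min(n_off, len(day_hours)), replace=False).tolist())
    hours = []
    for h in range(24):
        if h not in range(7, 22):
            hours.append(HourPlan(0.0, 0.0, 0.0, "rest"))
        elif h in off_hours:
            if rng.random() < sched.p_shortstep:
                c = float(rng.uniform(*sched.shortstep_cadence))
                lbl = "off_shortstep"
            else:
                c = float(rng.uniform(*sched.brady_cadence))
                lbl = "off_bradykinetic"
            a = float(rng.uniform(*sched.off_amplitude))
            hours.append(HourPlan(walking_minutes, c, a, lbl))
        elif rng.random() < sched.p_activity_hour:
            c = float(rng.uniform(*sched.activity_cadence))
            a = float(rng.uniform(*sched.activity_amplitude))
            hours.append(HourPlan(walking_minutes, c, a, "activity"))
        else:
            # In-band with margin so detection error cannot cross a cut-off.
            c = float(np.clip(rng.normal(110.0, 4.0), 103.0, 117.0))
            a = float(max(2.2, 2.78 * (1.0 + rng.normal(0.0, normal_amp_cv))))
            hours.append(HourPlan(walking_minutes, c, a, "normal"))
    return DailyPlan(hours=hours, seed=seed, subject_id=subject_id)


def diary_from_truth(
    truth: GroundTruth, awareness: float, rng: np.random.Generator
) -> DiaryDay:
    """Diary implied by the planted truth under imperfect self-awareness.

    Each true off hour is reported as subjectively off ('bad' or
    'not_good') with probability ``awareness``; all other hours read 'good'.
    """
    states = {}
    for h, lbl in zip(truth.hours, truth.labels):
        if lbl in OFF_SEGMENTS and rng.random() < awareness:
            states[h] = "bad" if rng.random() < 0.5 else "not_good"
        else:
            states[h] = "good"
    return DiaryDay(states=states, subject_id=truth.subject_id)


def generate_cohort(
    n_patients: int,
    n_controls: int,
    off_schedule: OffSchedule | None = None,
    seed: int = 0,
    awareness: float = 1.0,
    walking_minutes: float = 10.0,
    control_hourly_amp_cv: float = 0.20,
    control_hourly_cadence_sd: float = 3.0,
    patient_normal_amp_cv: float = 0.03,
    n_hours: int = 24,
    id_prefix: str = "",
) -> list[SubjectRecord]:
    """Simulate a cohort of patients (with planted off hours) and controls.

    Controls are drawn around the reference control geometry (cadence
    110 ± 12 steps/min, acceleration 2.78 ± 0.42 m/s²) and contain no off
    hours; patients get off hours per ``off_schedule``. Diaries follow the
    planted truth through an ``awareness`` probability, so desynchronisation
    scenarios can be planted directly. ``n_hours`` < 24 truncates every
    plan (keeping the same clock hours) for quick runs.
    """
    if n_patients < 0 or n_controls < 0 or n_patients + n_controls == 0:
        raise InvalidParameterError("cohort must contain at least one subject")
    sched = off_schedule or OffSchedule()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_patients + n_controls)
    records = []
    for k in range(n_patients + n_controls):
        is_patient = k < n_patients
        sid = (f"{id_prefix}"
               f"{'pd' if is_patient else 'ctl'}"
               f"{k if is_patient else k - n_patients:03d}")
        rng = np.random.default_rng(children[k])
        plan_seed = int(rng.integers(0, 2**31 - 1))
        if is_patient:
            plan = _patient_plan(rng, plan_seed, sid, sched, walking_minutes,
                                 patient_normal_amp_cv)
        else:
            plan = _control_plan(rng, plan_seed, sid, walking_minutes,
                                 control_hourly_amp_cv, control_hourly_cadence_sd)
        if n_hours < 24:
            # keep daytime (walking) clock hours so short runs still carry gait
            start = 8
            plan = replace(
                plan, hours=plan.hours[start : start + n_hours], start_hour=start
            )
        trace, truth = generate_trace(plan)
        diary = diary_from_truth(truth, awareness if is_patient else 0.0, rng)
        records.append(SubjectRecord(sid, "patient" if is_patient else "control",
                                     trace, truth, diary, plan))
    return records
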