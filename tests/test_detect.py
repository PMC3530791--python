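"""Step detection: magnitude, template extraction, pattern matching."""

import itertools

import numpy as np
import pytest

from gaitrhythm.detect import (
    AccelTrace,
    StepTemplate,
    extract_template,
    magnitude,
    match_steps,
    step_intervals,
)
from gaitrhythm.errors import InvalidParameterError, NoTemplateError
from gaitrhythm.simulate import generate_trace, synth_step_waveform

from conftest import trace_from_magnitude, walking_plan


def half_peak_events(mag, peak, dt, min_height_ratio=0.5):
    """Oracle: sample index of the maximum inside each region above half-peak."""
    above = mag > min_height_ratio * peak
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = edges[::2] + 1 if above[0] is np.True_ else None
    # robust region extraction
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return np.array([])
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    return np.array([s[np.argmax(mag[s])] for s in splits])


class TestMagnitude:
    def test_pythagorean_triple(self):
        tr = AccelTrace(np.array([[0.6, 0.8, 0.0], [0.0, 0.0, 0.0]]))
        assert magnitude(tr) == pytest.approx([1.0, 0.0])

    def test_matches_elementwise_bruteforce(self, rng):
        s = rng.normal(size=(500, 3))
        tr = AccelTrace(s)
        brute = np.array([np.sqrt(x * x + y * y + z * z) for x, y, z in s])
        assert np.max(np.abs(magnitude(tr) - brute)) == 0.0

    def test_nonfinite_sample_names_index(self, rng):
        s = rng.normal(size=(50, 3))
        s[17, 1] = np.nan
        with pytest.raises(InvalidParameterError, match="17"):
            magnitude(AccelTrace(s))

    def test_invariant_under_axis_permutation_and_sign(self, rng):
        s = rng.normal(size=(200, 3))
        base = magnitude(AccelTrace(s))
        for perm in itertools.permutations(range(3)):
            for signs in itertools.product([1, -1], repeat=3):
                t = s[:, perm] * np.array(signs)
                assert np.allclose(magnitude(AccelTrace(t)), base, atol=1e-12)


class TestExtractTemplate:
    def test_recovers_planted_pulse_shape(self, clean_walk):
        trace, _ = clean_walk
        template = extract_template(trace)
        pulse = synth_step_waveform(2.78, 0.3, 0.01)
        # align by peak and compare over the pulse support
        tpl = template.waveform
        k = int(np.argmax(tpl)) - int(np.argmax(pulse))
        seg = tpl[k : k + pulse.size]
        assert seg.size == pulse.size
        assert np.max(np.abs(seg - pulse)) < 0.05 * pulse.max()

    def test_pure_noise_has_no_template(self, rng):
        tr = AccelTrace(rng.normal(0, 0.2, size=(60_000, 3)))
        with pytest.raises(NoTemplateError):
            extract_template(tr)

    def test_deterministic(self, noisy_walk):
        trace, _ = noisy_walk
        t1 = extract_template(trace)
        t2 = extract_template(trace)
        assert np.array_equal(t1.waveform, t2.waveform)

    def test_empty_template_rejected(self):
        with pytest.raises(InvalidParameterError):
            StepTemplate(np.array([]))
        with pytest.raises(InvalidParameterError):
            StepTemplate(-np.ones(10))


class TestMatchSteps:
    def test_trace_equal_to_template_single_perfect_match(self):
        pulse = synth_step_waveform(2.0, 0.3, 0.01)
        trace = trace_from_magnitude(pulse)
        template = StepTemplate(pulse)
        series = match_steps(trace, template)
        assert series.n_events == 1
        assert series.correlations[0] == pytest.approx(1.0, abs=1e-9)
        assert series.amplitudes[0] == pytest.approx(2.0, abs=1e-9)

    def test_template_longer_than_trace_rejected(self):
        pulse = synth_step_waveform(2.0, 0.3, 0.01)
        trace = trace_from_magnitude(pulse[:10])
        with pytest.raises(InvalidParameterError, match="longer"):
            match_steps(trace, StepTemplate(pulse))

    @pytest.mark.parametrize("bad", [{"min_correlation": 0.0},
                                     {"min_correlation": 1.5},
                                     {"refractory": 0.0}])
    def test_parameter_ranges(self, bad):
        pulse = synth_step_waveform(2.0, 0.3, 0.01)
        trace = trace_from_magnitude(np.tile(pulse, 4))
        with pytest.raises(InvalidParameterError):
            match_steps(trace, StepTemplate(pulse), **bad)

    def test_planted_steps_recovered_with_high_precision_recall(self, noisy_walk):
        trace, truth = noisy_walk
        series = match_steps(trace, extract_template(trace))
        matched = 0
        det = series.times
        for t in truth.step_times:
            if np.min(np.abs(det - t)) <= 0.05:
                matched += 1
        recall = matched / truth.step_times.size
        # precision: detected events near a planted step
        near = sum(np.min(np.abs(truth.step_times - t)) <= 0.05 for t in det)
        precision = near / det.size
        assert recall >= 0.95
        assert precision >= 0.95

    def test_noiseless_events_match_half_peak_oracle(self, clean_walk):
        trace, truth = clean_walk
        a = magnitude(trace)
        oracle = half_peak_events(a, 2.78, 0.01)
        series = match_steps(trace, extract_template(trace))
        det_idx = np.round(series.times / 0.01).astype(int)
        assert det_idx.size == oracle.size
        assert np.max(np.abs(det_idx - oracle)) <= 1

    def test_artifacts_in_rest_hour_stay_below_gait_threshold(self):
        """Generator artifact bursts are not mistaken for gait.

        A rest hour containing only sensor noise and non-periodic artifact
        bursts must yield far fewer accepted events than the 20-step
        validity threshold, so it can never masquerade as a walking hour.
        """
        from gaitrhythm.simulate import DailyPlan, HourPlan, canonical_template

        plan = DailyPlan(hours=[HourPlan(0.0, 0.0, 0.0, "rest")], seed=4,
                         artifact_rate=10.0)
        trace, _ = generate_trace(plan)
        series = match_steps(trace, canonical_template(), min_correlation=0.6)
        from gaitrhythm.hourly import MIN_STEPS_PER_HOUR

        assert series.n_events < MIN_STEPS_PER_HOUR

    def test_doubling_axes_doubles_amplitudes_not_times(self, noisy_walk):
        trace, _ = noisy_walk
        template = extract_template(trace)
        s1 = match_steps(trace, template)
        doubled = AccelTrace(trace.samples * 2.0,
                             sample_interval=trace.sample_interval)
        s2 = match_steps(doubled, template)
        assert np.array_equal(s1.times, s2.times)
        assert np.allclose(s2.amplitudes, 2.0 * s1.amplitudes, rtol=1e-12)


class TestStepIntervals:
    def test_uniform_spacing(self):
        s = _series([0.0, 0.545, 1.090])
        assert step_intervals(s) == pytest.approx([0.545, 0.545])

    def test_gap_discarded_as_bout_boundary(self):
        s = _series([0.0, 0.5, 10.0])
        assert step_intervals(s, max_gap=2.0) == pytest.approx([0.5])

    def test_empty_and_singleton(self):
        assert step_intervals(_series([])).size == 0
        assert step_intervals(_series([1.0])).size == 0

    def test_cadence_from_intervals_matches_planted(self, noisy_walk):
        trace, truth = noisy_walk
        series = match_steps(trace, extract_template(trace))
        iv = step_intervals(series)
        cadence = 60.0 / iv.mean()
        assert cadence == pytest.approx(110.0, abs=2.0)


def _series(times):
    from gaitrhythm.detect import StepSeries

    t = np.asarray(times, dtype=float)
    return StepSeries(times=t, amplitudes=np.ones_like(t),
                      correlations=np.ones_like(t))
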