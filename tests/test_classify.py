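"""Hour labelling rules and patient-level classification."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitrhythm.classify import (
    Category,
    HourLabel,
    Label,
    classify_patient,
    label_hour,
    label_hours,
    recover_planted,
)
from gaitrhythm.errors import InsufficientDataError, InvalidParameterError
from gaitrhythm.hourly import AccelCV, HourlyProfile, HourRecord
from gaitrhythm.norms import REFERENCE_CUTOFFS


def labels_from(pairs):
    return [HourLabel(h, lbl) for h, lbl in pairs]


CV_OK = AccelCV(cv=0.10, n_hours=6)


class TestLabelHour:
    @pytest.mark.parametrize(
        "cadence,accel,expected",
        [
            (80.0, 1.5, Label.OFF_BRADYKINETIC),  # slow + weak push-off
            (130.0, 1.5, Label.OFF_SHORTSTEP),  # festinating small steps
            (130.0, 3.2, Label.ACTIVITY_RELATED),  # brisk purposeful walking
            (110.0, 1.0, Label.NORMAL),  # in-band cadence is never off
            (80.0, 2.5, Label.UNCONFIRMED_DEVIATION),  # no accel corroboration
            (110.0, 2.78, Label.NORMAL),
        ],
    )
    def test_decision_regions(self, cadence, accel, expected):
        assert label_hour(cadence, accel, REFERENCE_CUTOFFS) is expected

    @pytest.mark.parametrize(
        "cadence,accel,expected",
        [
            (98.0, 1.5, Label.NORMAL),  # at the low cut-off: not below it
            (122.0, 1.5, Label.NORMAL),  # at the high cut-off
            (97.999, 1.94, Label.UNCONFIRMED_DEVIATION),  # accel at cut-off: not below
            (122.001, 1.94, Label.ACTIVITY_RELATED),
        ],
    )
    def test_strict_cutoff_boundaries(self, cadence, accel, expected):
        assert label_hour(cadence, accel, REFERENCE_CUTOFFS) is expected

    @given(cadence=st.floats(40.0, 180.0), accel=st.floats(0.1, 6.0))
    @settings(max_examples=200, deadline=None)
    def test_partition_exhaustive_exclusive(self, cadence, accel):
        """Every (cadence, acceleration) pair gets exactly one valid label."""
        lbl = label_hour(cadence, accel, REFERENCE_CUTOFFS)
        assert lbl in set(Label) - {Label.SPARSE}

    @given(cadence=st.floats(40.0, 97.9), accel=st.floats(0.1, 1.9),
           drop=st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_lowering_off_hour_acceleration_keeps_it_off(self, cadence, accel, drop):
        before = label_hour(cadence, accel, REFERENCE_CUTOFFS)
        after = label_hour(cadence, max(accel - drop, 0.01), REFERENCE_CUTOFFS)
        assert before is Label.OFF_BRADYKINETIC
        assert after is Label.OFF_BRADYKINETIC

    def test_high_cadence_high_accel_never_off(self):
        for cadence in (123.0, 140.0, 170.0):
            assert label_hour(cadence, 3.5, REFERENCE_CUTOFFS) is Label.ACTIVITY_RELATED


class TestLabelHours:
    def test_sparse_iff_invalid(self):
        prof = HourlyProfile(hours=[
            HourRecord(0, 5, None, None, False),
            HourRecord(1, 500, 110.0, 2.7, True),
        ])
        labels = label_hours(prof, REFERENCE_CUTOFFS)
        assert labels[0].label is Label.SPARSE
        assert labels[1].label is Label.NORMAL


class TestClassifyPatient:
    def test_all_normal_low_cv_is_definite_good(self):
        """CV 0.13 with in-band cadence all day: definite gait good."""
        labels = labels_from([(h, Label.NORMAL) for h in range(8, 20)])
        asmt = classify_patient(labels, AccelCV(0.13, 12), REFERENCE_CUTOFFS)
        assert asmt.category is Category.DEFINITE_GAIT_GOOD
        assert asmt.gait_off_hours == set()

    def test_all_normal_high_cv_is_reserved(self):
        """CV 0.27 exceeds the 0.24 cut-off: assessment reserved."""
        labels = labels_from([(h, Label.NORMAL) for h in range(8, 20)])
        asmt = classify_patient(labels, AccelCV(0.27, 12), REFERENCE_CUTOFFS)
        assert asmt.category is Category.RESERVED_PROBABLE_GOOD

    def test_cv_boundary_is_strict(self):
        labels = labels_from([(h, Label.NORMAL) for h in range(8, 20)])
        asmt = classify_patient(labels, AccelCV(REFERENCE_CUTOFFS.cv_max, 12),
                                REFERENCE_CUTOFFS)
        assert asmt.category is Category.RESERVED_PROBABLE_GOOD

    def test_single_off_hour_suffices(self):
        labels = labels_from([(8, Label.NORMAL), (9, Label.OFF_BRADYKINETIC),
                              (10, Label.NORMAL)])
        asmt = classify_patient(labels, CV_OK, REFERENCE_CUTOFFS)
        assert asmt.category is Category.DEFINITE_GAIT_OFF
        assert asmt.gait_off_hours == {9}

    def test_unconfirmed_deviation_reserves(self):
        labels = labels_from([(8, Label.UNCONFIRMED_DEVIATION)] +
                             [(h, Label.NORMAL) for h in range(9, 15)])
        asmt = classify_patient(labels, CV_OK, REFERENCE_CUTOFFS)
        assert asmt.category is Category.RESERVED_PROBABLE_OFF

    def test_activity_hours_do_not_block_gait_good(self):
        labels = labels_from([(8, Label.ACTIVITY_RELATED)] +
                             [(h, Label.NORMAL) for h in range(9, 15)])
        asmt = classify_patient(labels, CV_OK, REFERENCE_CUTOFFS)
        assert asmt.category is Category.DEFINITE_GAIT_GOOD

    def test_order_invariance(self):
        pairs = [(9, Label.OFF_SHORTSTEP), (8, Label.NORMAL), (12, Label.SPARSE),
                 (10, Label.ACTIVITY_RELATED)]
        a = classify_patient(labels_from(pairs), CV_OK, REFERENCE_CUTOFFS)
        b = classify_patient(labels_from(pairs[::-1]), CV_OK, REFERENCE_CUTOFFS)
        assert a.category is b.category
        assert a.gait_off_hours == b.gait_off_hours

    def test_insufficient_valid_hours(self):
        labels = labels_from([(8, Label.NORMAL), (9, Label.SPARSE)])
        with pytest.raises(InsufficientDataError):
            classify_patient(labels, CV_OK, REFERENCE_CUTOFFS)


class TestRecoverPlanted:
    def test_constructed_confusion_counts(self):
        from gaitrhythm.simulate import GroundTruth

        def truth(off_hours, n_hours=4):
            labels = ["off_bradykinetic" if h in off_hours else "normal"
                      for h in range(n_hours)]
            return GroundTruth(hours=list(range(n_hours)), labels=labels,
                               cadences=[100.0] * n_hours,
                               amplitudes=[2.0] * n_hours,
                               diary_states=["good"] * n_hours)

        def asmt(off_hours, n_hours=4):
            labels = labels_from([
                (h, Label.OFF_BRADYKINETIC if h in off_hours else Label.NORMAL)
                for h in range(n_hours)
            ])
            return classify_patient(labels, CV_OK, REFERENCE_CUTOFFS)

        summary = recover_planted(
            [asmt({1}), asmt(set()), asmt({2, 3})],
            [truth({1}), truth({0}), truth({2})],
        )
        assert summary["hour"]["tp"] == 2  # hour 1 of p0, hour 2 of p2
        assert summary["hour"]["fn"] == 1  # hour 0 of p1 missed
        assert summary["hour"]["fp"] == 1  # hour 3 of p2 spurious
        assert summary["patient"]["sensitivity"] == pytest.approx(2 / 3)

    def test_misaligned_lists_rejected(self):
        with pytest.raises(InvalidParameterError):
            recover_planted([], [object()])
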