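"""Rule-based labelling of hours and classification of patients.

Each valid hour lands in exactly one region of the (cadence, acceleration)
plane relative to the control cut-offs:

* cadence below the band with low acceleration → bradykinetic gait off;
* cadence above the band with low acceleration → short-stepping /
  festinating / freezing gait off;
* cadence above the band with non-low acceleration → activity-related
  (fast purposeful walking raises both parameters; excluded from off);
* cadence outside the band otherwise → unconfirmed deviation (the cadence
  change lacks the corroborating acceleration drop);
* cadence inside the band → normal, regardless of acceleration;
* hours with too few steps → sparse.

A patient with any off-labelled hour is "definite gait off". With no off
hour but an unconfirmed deviation the assessment is reserved. A patient
whose cadence never leaves the band is "definite gait good" only if the
day-long acceleration CV stays below its cut-off; otherwise reserved.
Reserved patients are excluded from diary-concordance analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

from .errors import InsufficientDataError, InvalidParameterError
from .hourly import AccelCV, HourlyProfile
from .norms import Cutoffs


class Label(str, Enum):
    NORMAL = "normal"
    ACTIVITY_RELATED = "activity_related"
    OFF_BRADYKINETIC = "off_bradykinetic"
    OFF_SHORTSTEP = "off_shortstep"
    UNCONFIRMED_DEVIATION = "unconfirmed_deviation"
    SPARSE = "sparse"


OFF_LABELS = frozenset({Label.OFF_BRADYKINETIC, Label.OFF_SHORTSTEP})


class Category(str, Enum):
    DEFINITE_GAIT_OFF = "definite_gait_off"
    DEFINITE_GAIT_GOOD = "definite_gait_good"
    RESERVED_PROBABLE_OFF = "reserved_probable_off"
    RESERVED_PROBABLE_GOOD = "reserved_probable_good"


@dataclass
class HourLabel:
    hour: int  # 0-23
    label: Label


@dataclass
class PatientAssessment:
    subject_id: str
    category: Category
    gait_off_hours: set[int]
    accel_cv: float
    hour_labels: list[HourLabel]


def label_hour(cadence: float, acceleration: float, cutoffs: Cutoffs) -> Label:
    """Label one valid hour's (cadence, acceleration) pair. Strict cut-offs."""
    low_accel = acceleration < cutoffs.accel_off
    if cadence < cutoffs.cadence_lo:
        return Label.OFF_BRADYKINETIC if low_accel else Label.UNCONFIRMED_DEVIATION
    if cadence > cutoffs.cadence_hi:
        return Label.OFF_SHORTSTEP if low_accel else Label.ACTIVITY_RELATED
    return Label.NORMAL


def label_hours(profile: HourlyProfile, cutoffs: Cutoffs) -> list[HourLabel]:
    """Label every hour of a profile; invalid hours are sparse."""
    out = []
    for h in profile.hours:
        if not h.valid:
            out.append(HourLabel(h.hour, Label.SPARSE))
        else:
            out.append(HourLabel(h.hour, label_hour(h.cadence, h.acceleration, cutoffs)))
    return out


def classify_patient(
    labels: list[HourLabel],
    cv: AccelCV,
    cutoffs: Cutoffs,
    subject_id: str = "",
) -> PatientAssessment:
    """Classify a patient from their hour labels and acceleration CV.

    Activity-related hours are excluded deviations, so a patient whose only
    out-of-band hours are activity-related can still be gait good.
    """
    counts = Counter(hl.label for hl in labels)
    n_valid = sum(v for k, v in counts.items() if k is not Label.SPARSE)
    if n_valid < 2:
        raise InsufficientDataError(f"need >= 2 valid hours; got {n_valid}")
    off_hours = {hl.hour for hl in labels if hl.label in OFF_LABELS}
    if off_hours:
        category = Category.DEFINITE_GAIT_OFF
    elif counts[Label.UNCONFIRMED_DEVIATION]:
        category = Category.RESERVED_PROBABLE_OFF
    elif cv.cv < cutoffs.cv_max:
        category = Category.DEFINITE_GAIT_GOOD
    else:
        category = Category.RESERVED_PROBABLE_GOOD
    return PatientAssessment(
        subject_id=subject_id,
        category=category,
        gait_off_hours=off_hours,
        accel_cv=cv.cv,
        hour_labels=list(labels),
    )


def recover_planted(
    assessments: list[PatientAssessment],
    truths: list["GroundTruth"],  # noqa: F821 - simulate.GroundTruth
) -> dict:
    """Confusion summary of detected vs planted off hours.

    Per-hour sensitivity/specificity pool all (patient, hour) pairs; planted
    off hours are those whose true label is an off type. Per-patient counts
    compare detected category against whether any off hour was planted.
    """
    if len(assessments) != len(truths):
        raise InvalidParameterError(
            f"{len(assessments)} assessments vs {len(truths)} ground truths"
        )
    tp = fp = tn = fn = 0
    pat_tp = pat_fp = pat_tn = pat_fn = 0
    for asmt, truth in zip(assessments, truths):
        true_off = truth.off_hours()
        pred_off = asmt.gait_off_hours
        all_hours = {hl.hour for hl in asmt.hour_labels} | true_off
        for h in all_hours:
            t, p = h in true_off, h in pred_off
            tp += t and p
            fn += t and not p
            fp += p and not t
            tn += not t and not p
        pat_true = bool(true_off)
        pat_pred = asmt.category is Category.DEFINITE_GAIT_OFF
        pat_tp += pat_true and pat_pred
        pat_fn += pat_true and not pat_pred
        pat_fp += pat_pred and not pat_true
        pat_tn += not pat_true and not pat_pred
    return {
        "hour": {
            "tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        },
        "patient": {
            "tp": pat_tp, "fp": pat_fp, "tn": pat_tn, "fn": pat_fn,
            "sensitivity": pat_tp / (pat_tp + pat_fn) if pat_tp + pat_fn else float("nan"),
            "specificity": pat_tn / (pat_tn + pat_fp) if pat_tn + pat_fp else float("nan"),
        },
    }
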