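"""Control-cohort reference statistics and decision cut-offs.

The motor-fluctuation rules are anchored to inter-subject statistics of a
healthy control cohort walking freely over a day:

* cadence band: mean ± 1 SD of the controls' subject-level mean cadences.
  The published control cohort gives 110 ± 12 steps/min, hence the band
  98–122 steps/min; hours outside it are fluctuation candidates.
* acceleration off cut-off: mean − 2 SD of the controls' subject-level mean
  gait accelerations (2.78 ± 0.42 m/s² → 1.94 m/s²). A candidate hour is a
  gait-off hour only when its acceleration also falls below this level,
  reflecting the loss of floor-reaction force in the off state.
* acceleration-CV cut-off: mean + 1 SD of the controls' acceleration CVs
  (0.20 ± 0.04 → 0.24). A patient whose cadence never leaves the band is
  "gait good" only when their day-long acceleration CV stays below it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidParameterError
from .hourly import HourlyProfile, acceleration_cv


@dataclass(frozen=True)
class ControlNorms:
    """Inter-subject mean/SD of control subject-level gait statistics."""

    cadence_mean: float  # steps/min
    cadence_sd: float
    accel_mean: float  # m/s²
    accel_sd: float
    cv_mean: float  # unitless
    cv_sd: float
    n_controls: int

    def __post_init__(self) -> None:
        if min(self.cadence_sd, self.accel_sd, self.cv_sd) < 0:
            raise InvalidParameterError("standard deviations must be >= 0")
        if self.n_controls < 2:
            raise InvalidParameterError("norms require >= 2 control subjects")


@dataclass(frozen=True)
class Cutoffs:
    """Decision thresholds derived from :class:`ControlNorms`.

    All comparisons downstream are strict: a value exactly at a cut-off is
    neither off nor good by that rule.
    """

    cadence_lo: float  # steps/min; below → bradykinetic candidate
    cadence_hi: float  # steps/min; above → short-stepping/activity candidate
    accel_off: float  # m/s²; below → off-consistent acceleration
    cv_max: float  # unitless; at/above → unusual day-long variability

    def __post_init__(self) -> None:
        if not self.cadence_lo < self.cadence_hi:
            raise InvalidParameterError("cadence_lo must be < cadence_hi")
        if not self.accel_off > 0:
            raise InvalidParameterError(
                "acceleration off cut-off must be positive; control data implausible"
            )


#: Published control-cohort statistics (n=17): cadence 110 ± 12 steps/min,
#: gait acceleration 2.78 ± 0.42 m/s², acceleration CV 0.20 ± 0.04.
REFERENCE_NORMS = ControlNorms(
    cadence_mean=110.0,
    cadence_sd=12.0,
    accel_mean=2.78,
    accel_sd=0.42,
    cv_mean=0.20,
    cv_sd=0.04,
    n_controls=17,
)


def compute_norms(
    control_profiles: list[HourlyProfile],
    ddof: int = 1,
    cv_ddof: int = 0,
) -> ControlNorms:
    """Inter-subject mean and SD of subject-level control statistics.

    Per control subject: mean cadence, mean acceleration, and acceleration
    CV over valid hours. The inter-subject spread uses the sample SD
    (``ddof=1``) by default.
    """
    if len(control_profiles) < 2:
        raise InsufficientDataError(
            f"need >= 2 control profiles; got {len(control_profiles)}"
        )
    cad, acc, cvs = [], [], []
    for p in control_profiles:
        if p.n_valid < 2:
            raise InsufficientDataError(
                f"control profile {p.subject_id!r} has {p.n_valid} valid hours; need >= 2"
            )
        cad.append(float(p.cadences().mean()))
        acc.append(float(p.accelerations().mean()))
        cvs.append(acceleration_cv(p, ddof=cv_ddof).cv)
    cad, acc, cvs = np.array(cad), np.array(acc), np.array(cvs)
    return ControlNorms(
        cadence_mean=float(cad.mean()),
        cadence_sd=float(cad.std(ddof=ddof)),
        accel_mean=float(acc.mean()),
        accel_sd=float(acc.std(ddof=ddof)),
        cv_mean=float(cvs.mean()),
        cv_sd=float(cvs.std(ddof=ddof)),
        n_controls=len(control_profiles),
    )


def derive_cutoffs(norms: ControlNorms) -> Cutoffs:
    """cadence mean ± 1 SD band, acceleration mean − 2 SD, CV mean + 1 SD."""
    return Cutoffs(
        cadence_lo=norms.cadence_mean - norms.cadence_sd,
        cadence_hi=norms.cadence_mean + norms.cadence_sd,
        accel_off=norms.accel_mean - 2.0 * norms.accel_sd,
        cv_max=norms.cv_mean + norms.cv_sd,
    )


#: Cut-offs from the published control statistics: <98 / >122 steps/min,
#: <1.94 m/s², CV <0.24.
REFERENCE_CUTOFFS = derive_cutoffs(REFERENCE_NORMS)
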