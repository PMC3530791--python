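"""Concordance between objective gait-off hours and subjective diaries.

Patients rate each hour of the day as ``good``, ``not_good`` or ``bad``;
hours rated not-good or bad are subjective off hours. A patient is
*synchronized* when at least one clock hour is both an objective gait-off
hour and a subjective off hour, *both good* when both hour sets are empty,
and *desynchronized* otherwise — covering both the patient who feels fine
while walking badly and the patient whose complaints fall at hours where
the gait parameters are normal.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .errors import InvalidParameterError, TraceFormatError
from .simulate import DiaryDay

DIARY_STATES = ("good", "not_good", "bad")
SUBJECTIVE_OFF_STATES = frozenset({"not_good", "bad"})


class Outcome(str, Enum):
    BOTH_GOOD = "both_good"
    SYNCHRONIZED = "synchronized"
    DESYNCHRONIZED = "desynchronized"


@dataclass
class SyncResult:
    patient_id: str
    gait_off_hours: set[int]
    subjective_off_hours: set[int]
    outcome: Outcome
    matched_hours: set[int]

    @property
    def subjective_off_group(self) -> bool:
        """True when the patient reported any subjective off hour."""
        return bool(self.subjective_off_hours)


def subjective_off_hours(diary: DiaryDay) -> set[int]:
    """Hours rated not-good or bad."""
    off = set()
    for hour, state in diary.states.items():
        if state not in DIARY_STATES:
            raise TraceFormatError(f"unknown diary state token {state!r} at hour {hour}")
        if state in SUBJECTIVE_OFF_STATES:
            off.add(int(hour))
    return off


def synchronize(
    gait_off: set[int], subj_off: set[int], patient_id: str = "", tolerance: int = 0
) -> SyncResult:
    """Compare an objective gait-off hour set with a subjective off hour set.

    ``tolerance`` (hours) optionally widens the match window; the default 0
    requires an exactly shared clock hour.
    """
    for h in gait_off | subj_off:
        if not 0 <= h <= 23:
            raise InvalidParameterError(f"hour {h} outside 0-23")
    if tolerance == 0:
        matched = gait_off & subj_off
    else:
        matched = {
            g for g in gait_off if any(abs(g - s) <= tolerance for s in subj_off)
        }
    if not gait_off and not subj_off:
        outcome = Outcome.BOTH_GOOD
    elif matched:
        outcome = Outcome.SYNCHRONIZED
    else:
        outcome = Outcome.DESYNCHRONIZED
    return SyncResult(patient_id, set(gait_off), set(subj_off), outcome, matched)


def cohort_summary(results: list[SyncResult]) -> dict:
    """Cohort counts and percentages of diary/gait concordance.

    Patients split by whether the diary reports any off hour. Within the
    subjective-good group, patients with objective gait-off hours form the
    "no consciousness of off" pattern.
    """
    if not results:
        raise InvalidParameterError("cohort_summary needs at least one result")
    n = len(results)
    n_desync = sum(r.outcome is Outcome.DESYNCHRONIZED for r in results)
    good = [r for r in results if not r.subjective_off_group]
    off = [r for r in results if r.subjective_off_group]
    good_with_gait_off = sum(bool(r.gait_off_hours) for r in good)
    good_both_good = sum(r.outcome is Outcome.BOTH_GOOD for r in good)
    off_sync = sum(r.outcome is Outcome.SYNCHRONIZED for r in off)
    off_desync = sum(r.outcome is Outcome.DESYNCHRONIZED for r in off)

    def pct(k: int, d: int) -> float:
        return 100.0 * k / d if d else float("nan")

    return {
        "n": n,
        "n_desynchronized": n_desync,
        "pct_desynchronized": pct(n_desync, n),
        "subjective_good": {
            "n": len(good),
            "n_with_gait_off": good_with_gait_off,
            "pct_with_gait_off": pct(good_with_gait_off, len(good)),
            "n_both_good": good_both_good,
            "pct_both_good": pct(good_both_good, len(good)),
        },
        "subjective_off": {
            "n": len(off),
            "n_synchronized": off_sync,
            "pct_synchronized": pct(off_sync, len(off)),
            "n_desynchronized": off_desync,
            "pct_desynchronized": pct(off_desync, len(off)),
        },
    }
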