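"""Reference cohort: 44 fluctuating-gait patients with objective and
subjective off hours.

This is a verbatim transcription of a published per-patient comparison
table (objective gait-off hours from waist-worn accelerometry vs
diary-reported subjective off hours, plus the printed concordance call) for
44 Parkinson's disease patients: 23 who noticed no fluctuation
("subjective good", rows 1-23) and 21 who did (rows 24-44). Hour tokens
are kept exactly as printed and normalised by :func:`_parse_hours`:
4-digit ``"0800"`` → 8, ``"2400"`` wraps to 0, bare integers (``"15"``)
are hours of day, and the 5-digit token ``"01500"`` in row 28 is treated
as a typo for 1500 (required for that row's printed "Both off at 1500").

Row 33's printed matched-hour list omits some members of the true hour-set
intersection; the transcription is left as printed and only the
concordance category is used for comparisons.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

from .diary import Outcome
from .errors import TraceFormatError

# (case number, gait off hours, subjective off hours, printed concordance)
_RAW_ROWS: list[tuple[int, str, str, str]] = [
    (1, "Good", "Good", "Both good"),
    (2, "Good", "Good", "Both good"),
    (3, "Good", "Good", "Both good"),
    (4, "Good", "Good", "Both good"),
    (5, "0600", "Good", "No"),
    (6, "0800", "Good", "No"),
    (7, "1600", "Good", "No"),
    (8, "1900", "Good", "No"),
    (9, "0400, 0500", "Good", "No"),
    (10, "0700, 1600", "Good", "No"),
    (11, "0200, 1900", "Good", "No"),
    (12, "2200, 2300", "Good", "No"),
    (13, "1000, 1300, 1800", "Good", "No"),
    (14, "1000, 1100, 1600", "Good", "No"),
    (15, "0100, 2000, 2100", "Good", "No"),
    (16, "1400, 1600, 1800, 2200", "Good", "No"),
    (17, "0600, 1700, 1900, 2000", "Good", "No"),
    (18, "0800, 0900, 1800, 2100", "Good", "No"),
    (19, "0500, 0700, 0800, 2000", "Good", "No"),
    (20, "0100, 0800, 1700, 1800, 2100", "Good", "No"),
    (21, "0800, 0900, 1800, 2100, 2400", "Good", "No"),
    (22, "0600, 0800, 0900, 1200, 1300, 1800, 1900, 2000, 2100", "Good", "No"),
    (23, "0500, 0600, 0700, 0800, 1200, 1800, 1900, 2000, 2100, 2200", "Good", "No"),
    (24, "0800", "0800, 2100", "Both off at 0800"),
    (25, "1300", "1200, 1300, 1600", "Both off at 1300"),
    (26, "1700, 1800", "1600, 1700", "Both off at 1700"),
    (27, "0800, 0900, 1400", "0600, 0700, 0800, 0900, 1000, 1100, 1200",
     "Both off at 0800, 0900"),
    (28, "0600, 0700, 01500", "1400, 1500, 1600, 1800", "Both off at 1500"),
    (29, "1500, 1800, 1900",
     "0600, 0700, 1300, 1400, 1800, 1900, 2000, 2100, 2200",
     "Both off at 1800, 1900"),
    (30, "0200, 0800, 1200, 1300", "0800", "Both off at 0800"),
    (31, "0800, 0900, 1500, 1700, 1900, 2000, 2400", "0900, 1000, 1100, 1300",
     "Both off at 0900"),
    (32, "0100, 0300, 0800, 1700, 1900, 2000", "0800", "Both off at 0800"),
    (33, "0700, 0800, 0900, 1100, 1200, 1700, 1800, 1900, 2000, 2100",
     "0800, 1200, 1400, 1500, 1800, 1900, 2000, 2100, 2200",
     "Both off at 1200, 1800, 2000, 2100"),
    (34, "Good", "0900, 1000, 1100, 1700, 1800, 1900", "No"),
    (35, "Good", "1200, 1300, 1400, 1500", "No"),
    (36, "Good", "1600", "No"),
    (37, "1500", "1000, 1100, 1800, 1900", "No"),
    (38, "1800", "15", "No"),
    (39, "2000", "13, 14, 15", "No"),
    (40, "0100, 0700, 0800", "11, 12, 13, 17, 18, 19, 23", "No"),
    (41, "0800, 0900, 1400", "16, 17, 18, 19, 20", "No"),
    (42, "0100, 0400, 1300, 2300", "5, 7, 15, 16, 17, 19, 20, 21", "No"),
    (43, "0400, 0600, 0700, 1500", "18", "No"),
    (44, "0300, 0600, 0700, 1600", "12, 13", "No"),
]

# Guards the transcription against accidental edits.
_CHECKSUM = "1dad00726d18e1829db97b2c141bb1bd"


@dataclass(frozen=True)
class ReferenceRecord:
    patient_id: int
    gait_off: frozenset[int]
    subjective_off: frozenset[int]
    printed_outcome: Outcome
    group: str  # 'subjective_good' | 'subjective_off'
    raw_gait: str
    raw_subjective: str


def _parse_hour_token(token: str) -> int:
    token = token.strip()
    if len(token) == 5 and token.startswith("0"):
        token = token[1:]  # '01500' → '1500' (documented transcription typo)
    if len(token) == 4 and token.isdigit():
        hh, mm = int(token[:2]), token[2:]
        if mm != "00":
            raise TraceFormatError(f"hour token {token!r} has non-zero minutes")
        return hh % 24  # '2400' wraps to hour 0 of the same recording day
    if token.isdigit() and 0 <= int(token) <= 23:
        return int(token)
    raise TraceFormatError(f"cannot parse hour token {token!r}")


def _parse_hours(cell: str) -> frozenset[int]:
    if cell.strip() == "Good":
        return frozenset()
    return frozenset(_parse_hour_token(t) for t in cell.split(","))


def _parse_outcome(cell: str) -> Outcome:
    if cell == "Both good":
        return Outcome.BOTH_GOOD
    if cell.startswith("Both off"):
        return Outcome.SYNCHRONIZED
    if cell == "No":
        return Outcome.DESYNCHRONIZED
    raise TraceFormatError(f"cannot parse concordance cell {cell!r}")


def load_reference_cohort() -> list[ReferenceRecord]:
    """Parse and return the 44 transcribed reference records.

    Raises :class:`TraceFormatError` if the embedded transcription no
    longer matches its checksum.
    """
    blob = "\n".join("\t".join(str(c) for c in row) for row in _RAW_ROWS)
    digest = hashlib.md5(blob.encode()).hexdigest()
    if digest != _CHECKSUM:
        raise TraceFormatError(
            f"reference-cohort transcription checksum mismatch ({digest})"
        )
    records = []
    for case, gait, subj, printed in _RAW_ROWS:
        records.append(
            ReferenceRecord(
                patient_id=case,
                gait_off=_parse_hours(gait),
                subjective_off=_parse_hours(subj),
                printed_outcome=_parse_outcome(printed),
                group="subjective_good" if case <= 23 else "subjective_off",
                raw_gait=gait,
                raw_subjective=subj,
            )
        )
    if len(records) != 44:
        raise TraceFormatError(f"expected 44 reference records; got {len(records)}")
    return records
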