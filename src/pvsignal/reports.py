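"""Core record types for spontaneous adverse-event reports.

A spontaneous report links one case (possibly submitted in several
versions) to a set of drugs, a non-empty set of reaction preferred terms
(PTs), demographics, outcome codes and dates.  These types are the
in-memory currency of the whole pipeline: parsers produce them, the
deduplicator and cohort filter consume and return them, and the
contingency builder counts them.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

__all__ = [
    "DrugEntry",
    "Reaction",
    "SafetyReport",
    "Quarter",
    "parse_quarter",
    "quarter_of",
    "parse_faers_date",
    "OUTCOME_CODES",
    "SEX_VALUES",
    "REPORTER_VALUES",
]

OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})
SEX_VALUES = ("female", "male", "unspecified")
REPORTER_VALUES = (
    "consumer",
    "pharmacist",
    "physician",
    "other-health-professional",
    "unspecified",
)

SUSPECT = "suspect"
CONCOMITANT = "concomitant"


@dataclass(frozen=True)
class DrugEntry:
    """One drug mention on a report."""

    name: str
    role: str = SUSPECT  # "suspect" or "concomitant"
    route: Optional[str] = None
    indication_pt: Optional[str] = None
    therapy_start: Optional[dt.date] = None


@dataclass(frozen=True)
class Reaction:
    """One adverse-event preferred term on a report, with optional onset date."""

    pt: str
    event_date: Optional[dt.date] = None


@dataclass
class SafetyReport:
    """One spontaneous adverse-event report (one case version).

    ``reactions`` is non-empty after ingestion; ``case_version`` >= 1.
    ``report_year`` is the receipt year and may be known even when the
    full ``receipt_date`` is not (year-only FAERS dates).
    """

    case_id: str
    case_version: int = 1
    receipt_date: Optional[dt.date] = None
    report_year: Optional[int] = None
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    sex: str = "unspecified"
    age_years: Optional[float] = None
    country: Optional[str] = None
    reporter: str = "unspecified"
    outcomes: frozenset[str] = frozenset()

    def pt_set(self) -> frozenset[str]:
        return frozenset(r.pt for r in self.reactions)

    def suspect_drugs(self) -> list[DrugEntry]:
        return [d for d in self.drugs if d.role == SUSPECT]

    def copy(self, **changes) -> "SafetyReport":
        return replace(self, **changes)


# --------------------------------------------------------------------------
# calendar quarters
# --------------------------------------------------------------------------

Quarter = tuple[int, int]  # (year, quarter 1..4)


def parse_quarter(text: str | Quarter) -> Quarter:
    """Parse '2016Q4' / '2016-Q4' / (2016, 4) into a (year, quarter) pair."""
    if isinstance(text, tuple):
        year, q = text
    else:
        s = str(text).upper().replace("-", "").strip()
        if "Q" not in s:
            raise ValueError(f"not a quarter: {text!r}")
        ys, qs = s.split("Q")
        year, q = int(ys), int(qs)
    if not 1 <= q <= 4:
        raise ValueError(f"quarter out of range: {text!r}")
    return (year, q)


def quarter_of(date: dt.date) -> Quarter:
    return (date.year, (date.month - 1) // 3 + 1)


# --------------------------------------------------------------------------
# FAERS partial dates
# --------------------------------------------------------------------------


def parse_faers_date(text: str | None) -> tuple[Optional[dt.date], Optional[int]]:
    """Parse a FAERS date field (YYYYMMDD, YYYYMM, YYYY, or ISO).

    Returns ``(date, year)``.  Month-precision dates map to the first day
    of the month (sufficient to place the report in a quarter); year-only
    dates return ``(None, year)``; unparseable text returns ``(None,
    None)``.  Callers that need day precision (time-to-onset) must check
    the original string length themselves or use :func:`parse_event_date`.
    """
    if text is None:
        return (None, None)
    s = str(text).strip().replace("-", "")
    if not s or not s.isdigit():
        return (None, None)
    try:
        if len(s) == 8:
            return (dt.date(int(s[:4]), int(s[4:6]), int(s[6:8])), int(s[:4]))
        if len(s) == 6:
            return (dt.date(int(s[:4]), int(s[4:6]), 1), int(s[:4]))
        if len(s) == 4:
            return (None, int(s))
    except ValueError:
        return (None, None)
    return (None, None)


def parse_event_date(text: str | None) -> Optional[dt.date]:
    """Parse an event/therapy date; partial dates count as missing.

    Day-level arithmetic (time-to-onset) would be fabricated for partial
    dates, so only full YYYYMMDD (or ISO) strings yield a date.
    """
    if text is None:
        return None
    s = str(text).strip().replace("-", "")
    if len(s) != 8 or not s.isdigit():
        return None
    try:
        return dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    except ValueError:
        return None


def in_window(report: SafetyReport, start: Quarter, end: Quarter) -> bool:
    if report.receipt_date is None:
        return False
    return start <= quarter_of(report.receipt_date) <= end


def validate_reports(reports: Iterable[SafetyReport]) -> None:
    for r in reports:
        if not r.reactions:
            raise ValueError(f"report {r.case_id}: empty reaction list")
        if r.case_version < 1:
            raise ValueError(f"report {r.case_id}: case_version < 1")
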