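"""Descriptive summaries of a report cohort.

Covers the standard pharmacovigilance characterization tables:
demographics (sex, age bands, reporter, country, route, reporting year),
time-to-onset (TTO) with the conventional <7 / 7–28 / 28–60 / >=60 day
bins, per-SOC fatality proportions, and yearly report counts.

Denominator conventions (documented because they differ by block): the
whole cohort for demographic fields and years; the TTO-classifiable row
count for TTO bins is also reported against the whole cohort so the
"unspecified" share is visible; the number of outcome *entries* for
outcome codes, since one report may carry several outcomes.
"""

from __future__ import annotations

import datetime as dt
import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import MedDRADictionary, _norm_key
from .reports import SafetyReport

__all__ = [
    "TTORecord",
    "round2",
    "summarize_demographics",
    "compute_tto",
    "summarize_tto",
    "death_proportion_by_soc",
    "yearly_counts",
]

TTO_BINS = ("<7", "7–28", "28–60", "≥60")  # half-open lower-inclusive
UNSPECIFIED = "unspecified"

AGE_BANDS = ("<20", "20–29", "30–39", "40–49", "50–59", "≥60")


def round2(x: float) -> float:
    """Round half-up to 2 decimals (deterministic display convention)."""
    return math.floor(x * 100 + 0.5) / 100


@dataclass(frozen=True)
class TTORecord:
    """Time-to-onset of the earliest event after the earliest therapy start."""

    case_id: str
    tto_days: Optional[int]
    bin: str

    def __post_init__(self) -> None:
        expected = _bin_of(self.tto_days)
        if self.bin != expected:
            raise ValueError(f"bin {self.bin!r} inconsistent with tto_days={self.tto_days}")


def _bin_of(days: Optional[int]) -> str:
    if days is None or days < 0:
        return UNSPECIFIED
    if days < 7:
        return TTO_BINS[0]
    if days < 28:
        return TTO_BINS[1]
    if days < 60:
        return TTO_BINS[2]
    return TTO_BINS[3]


def compute_tto(report: SafetyReport, drug: str) -> TTORecord:
    """TTO in whole days for the target drug; negative or missing → unspecified.

    Uses the earliest recorded event date minus the earliest therapy
    start among the report's entries for the target drug.
    """
    drug_key = _norm_key(drug)
    starts = [
        d.therapy_start
        for d in report.drugs
        if d.therapy_start is not None and _norm_key(d.name) == drug_key
    ]
    events = [r.event_date for r in report.reactions if r.event_date is not None]
    if not starts or not events:
        return TTORecord(report.case_id, None, UNSPECIFIED)
    days = (min(events) - min(starts)).days
    if days < 0:
        return TTORecord(report.case_id, None, UNSPECIFIED)
    return TTORecord(report.case_id, days, _bin_of(days))


def _count_block(block: str, counts: Counter, order: Sequence[str], denom: int) -> list[dict]:
    rows = []
    for cat in order:
        n = counts.get(cat, 0)
        rows.append(
            {"block": block, "category": cat, "count": n, "pct": round2(100 * n / denom)}
        )
    return rows


def summarize_demographics(cohort: Sequence[SafetyReport]) -> dict[str, object]:
    """Category counts/percentages plus the age median and IQR.

    Returns ``{"table": DataFrame(block, category, count, pct),
    "age_median": float, "age_q1": float, "age_q3": float}``.  Percentages
    use |cohort| as denominator except for the outcomes block, which uses
    the number of outcome entries.  Quantiles interpolate linearly
    between order statistics.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    n = len(cohort)
    rows: list[dict] = []

    sex = Counter(r.sex for r in cohort)
    rows += _count_block("sex", sex, ("female", "male", UNSPECIFIED), n)

    ages = [r.age_years for r in cohort if r.age_years is not None]
    age_bands: Counter[str] = Counter()
    for r in cohort:
        if r.age_years is None:
            age_bands[UNSPECIFIED] += 1
        elif r.age_years < 20:
            age_bands[AGE_BANDS[0]] += 1
        elif r.age_years >= 60:
            age_bands[AGE_BANDS[5]] += 1
        else:
            age_bands[AGE_BANDS[1 + int((r.age_years - 20) // 10)]] += 1
    rows += _count_block("age_band", age_bands, AGE_BANDS + (UNSPECIFIED,), n)

    reporter = Counter(r.reporter for r in cohort)
    rows += _count_block(
        "reporter",
        reporter,
        ("consumer", "pharmacist", "physician", "other-health-professional", UNSPECIFIED),
        n,
    )

    country = Counter(r.country or UNSPECIFIED for r in cohort)
    rows += _count_block(
        "country", country, [c for c, _ in country.most_common()], n
    )

    def cohort_route(r: SafetyReport) -> str:
        for d in r.suspect_drugs():
            if d.route:
                return d.route.casefold()
        return UNSPECIFIED

    route = Counter(cohort_route(r) for r in cohort)
    rows += _count_block("route", route, [c for c, _ in route.most_common()], n)

    outcome_entries = Counter()
    for r in cohort:
        outcome_entries.update(r.outcomes)
    n_entries = sum(outcome_entries.values())
    if n_entries:
        rows += _count_block(
            "outcomes", outcome_entries, sorted(outcome_entries), n_entries
        )

    years = Counter(str(r.report_year) for r in cohort if r.report_year is not None)
    rows += _count_block("year", years, sorted(years), n)

    table = pd.DataFrame(rows, columns=["block", "category", "count", "pct"])
    if ages:
        q1, med, q3 = np.percentile(ages, [25, 50, 75])
    else:
        q1 = med = q3 = math.nan
    return {"table": table, "age_median": float(med), "age_q1": float(q1), "age_q3": float(q3)}


def summarize_tto(cohort: Sequence[SafetyReport], drug: str) -> dict[str, object]:
    """TTO bin counts (with cohort-share percentages) and median/IQR in days."""
    records = [compute_tto(r, drug) for r in cohort]
    n = len(records)
    counts = Counter(rec.bin for rec in records)
    rows = _count_block("tto", counts, TTO_BINS + (UNSPECIFIED,), n)
    days = [rec.tto_days for rec in records if rec.tto_days is not None]
    if days:
        q1, med, q3 = np.percentile(days, [25, 50, 75])
    else:
        q1 = med = q3 = math.nan
    return {
        "table": pd.DataFrame(rows, columns=["block", "category", "count", "pct"]),
        "tto_median": float(med),
        "tto_q1": float(q1),
        "tto_q3": float(q3),
        "n_classifiable": len(days),
    }


def death_proportion_by_soc(
    cohort: Sequence[SafetyReport], dictionary: MedDRADictionary
) -> pd.DataFrame:
    """Per-SOC fatality: reports, death reports (outcome DE), percentage.

    A report counts toward every SOC its PTs map to; SOCs with no cohort
    reports are omitted.  Rows sort by ascending death proportion, then
    SOC name.
    """
    totals: Counter[str] = Counter()
    deaths: Counter[str] = Counter()
    for r in cohort:
        socs = {dictionary.soc_of(pt) for pt in r.pt_set()}
        is_death = "DE" in r.outcomes
        for soc in socs:
            totals[soc] += 1
            if is_death:
                deaths[soc] += 1
    rows = [
        {
            "soc": soc,
            "deaths": deaths.get(soc, 0),
            "total": total,
            "death_pct": round2(100 * deaths.get(soc, 0) / total),
        }
        for soc, total in totals.items()
    ]
    df = pd.DataFrame(rows, columns=["soc", "deaths", "total", "death_pct"])
    return df.sort_values(["death_pct", "soc"], ignore_index=True)


def yearly_counts(cohort: Sequence[SafetyReport]) -> pd.DataFrame:
    """Reports per receipt year with percentage of the cohort."""
    if not cohort:
        raise ValueError("cohort is empty")
    n = len(cohort)
    years = Counter(r.report_year for r in cohort if r.report_year is not None)
    rows = [
        {"year": y, "count": c, "pct": round2(100 * c / n)} for y, c in sorted(years.items())
    ]
    return pd.DataFrame(rows, columns=["year", "count", "pct"])
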