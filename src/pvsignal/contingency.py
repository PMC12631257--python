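"""Two-by-two (four-grid) contingency tables for drug–event pairs.

For a target cohort (reports with the drug of interest) against a
background (all other reports), each adverse event ``e`` gets counts

=====  ===========================================
a      cohort reports mentioning ``e``
b      cohort reports not mentioning ``e``
c      background reports mentioning ``e``
d      background reports not mentioning ``e``
=====  ===========================================

with ``N = a+b+c+d`` and expected count ``E = (a+b)(a+c)/N`` under
row/column independence.  The counting unit is the distinct (report,
event) pair: a report contributes at most once to an event even if the
PT repeats, and at SOC level once per distinct SOC among its PTs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import MedDRADictionary
from .reports import SafetyReport

__all__ = ["ContingencyTable", "build_tables", "observed_expected_all_pairs"]


@dataclass(frozen=True)
class ContingencyTable:
    """Four-grid counts for one drug–event pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.N == 0:
            raise ValueError("empty table")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def E(self) -> float:
        """Expected count of cell ``a`` under independence."""
        return (self.a + self.b) * (self.a + self.c) / self.N


def _event_sets(
    reports: Sequence[SafetyReport], level: str, dictionary: MedDRADictionary | None
) -> list[frozenset[str]]:
    if level == "PT":
        return [r.pt_set() for r in reports]
    if level == "SOC":
        if dictionary is None:
            raise ValueError("SOC-level tables need a PT->SOC dictionary")
        return [frozenset(dictionary.soc_of(pt) for pt in r.pt_set()) for r in reports]
    raise ValueError(f"level must be 'PT' or 'SOC', got {level!r}")


def build_tables(
    cohort: Sequence[SafetyReport],
    background: Sequence[SafetyReport],
    level: str = "PT",
    dictionary: MedDRADictionary | None = None,
) -> dict[str, ContingencyTable]:
    """Build one table per event observed in the cohort (a >= 1).

    Events never reported in the cohort get no table here; any minimum-
    count gate (e.g. a >= 3 for signal evaluation) is applied downstream
    so descriptive counts stay complete.
    """
    if not cohort or not background:
        raise ValueError("cohort and background must both be non-empty")
    cohort_events = _event_sets(cohort, level, dictionary)
    bg_events = _event_sets(background, level, dictionary)
    a_counts: Counter[str] = Counter()
    for ev in cohort_events:
        a_counts.update(ev)
    c_counts: Counter[str] = Counter()
    for ev in bg_events:
        c_counts.update(ev)
    n_cohort, n_bg = len(cohort), len(background)
    return {
        event: ContingencyTable(
            a=a, b=n_cohort - a, c=c_counts.get(event, 0), d=n_bg - c_counts.get(event, 0)
        )
        for event, a in sorted(a_counts.items())
    }


def tables_to_frame(tables: dict[str, ContingencyTable], level: str = "PT") -> pd.DataFrame:
    rows = [
        {"event": e, "level": level, "a": t.a, "b": t.b, "c": t.c, "d": t.d, "N": t.N, "E": t.E}
        for e, t in tables.items()
    ]
    return pd.DataFrame(rows, columns=["event", "level", "a", "b", "c", "d", "N", "E"])


def observed_expected_all_pairs(
    reports: Sequence[SafetyReport],
    min_drug_reports: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed/expected counts over every (suspect drug, PT) pair in a database.

    This is the cell population an empirical-Bayes prior is fitted on:
    for each drug g with n_g reports and each PT e with n_e reports among
    N total, the observed pair count a_ge and its expectation
    E_ge = n_g * n_e / N.  All drug-event combinations are included,
    zeros too, since the shrinkage prior must describe the full cell
    distribution.
    """
    N = len(reports)
    if N == 0:
        raise ValueError("no reports")
    drug_sets = [frozenset(d.name for d in r.suspect_drugs()) for r in reports]
    pt_sets = [r.pt_set() for r in reports]
    n_drug: Counter[str] = Counter()
    for s in drug_sets:
        n_drug.update(s)
    n_pt: Counter[str] = Counter()
    for s in pt_sets:
        n_pt.update(s)
    drugs = sorted(g for g, n in n_drug.items() if n >= min_drug_reports)
    pts = sorted(n_pt)
    joint: Counter[tuple[str, str]] = Counter()
    for ds, ps in zip(drug_sets, pt_sets):
        for g in ds:
            for e in ps:
                joint[(g, e)] += 1
    a = np.array([[joint.get((g, e), 0) for e in pts] for g in drugs], dtype=float)
    E = np.outer(
        [n_drug[g] for g in drugs], [n_pt[e] for e in pts]
    ).astype(float) / N
    return a.ravel(), E.ravel()
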