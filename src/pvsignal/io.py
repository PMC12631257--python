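"""Ingestion of FAERS-style report databases.

Two tabular dialects are supported:

* ``faers-ascii`` — the FDA quarterly layout: six "$"-delimited files
  (DEMO, DRUG, REAC, INDI, OUTC, THER) linked by ``primaryid``.  DEMO and
  REAC are mandatory; the other four are optional and their fields simply
  stay missing.
* ``normalized-csv`` — this package's three-table long format
  (``reports.csv``, ``drugs.csv``, ``reactions.csv``) linked by
  ``(case_id, case_version)``, which round-trips every field of
  :class:`~pvsignal.reports.SafetyReport` bit-exactly.

The module also owns drug-name standardization via a synonym table, the
two-stage case deduplication (latest case version, then collapse of
cross-identifier field duplicates), cohort extraction by suspect drug +
indication + quarter window, and PT→SOC dictionary lookup.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .reports import (
    CONCOMITANT,
    SUSPECT,
    DrugEntry,
    Quarter,
    Reaction,
    SafetyReport,
    in_window,
    parse_event_date,
    parse_faers_date,
    parse_quarter,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MedDRADictionary",
    "SynonymTable",
    "read_reports",
    "write_reports",
    "standardize_drug_names",
    "deduplicate",
    "filter_cohort",
    "map_pt_to_soc",
    "UNMAPPED",
]

UNMAPPED = "UNMAPPED"

_FAERS_FILES = ("DEMO", "DRUG", "REAC", "INDI", "OUTC", "THER")
_MANDATORY = ("DEMO", "REAC")

_SEX_CODES = {"F": "female", "M": "male"}
_OCCP_CODES = {
    "CN": "consumer",
    "PH": "pharmacist",
    "MD": "physician",
    "OT": "other-health-professional",
    "HP": "other-health-professional",
}
_ROLE_CODES = {"PS": SUSPECT, "SS": SUSPECT, "C": CONCOMITANT, "I": CONCOMITANT}


def _norm_key(s: str) -> str:
    """Case-insensitive, whitespace-normalized lookup key."""
    return " ".join(str(s).split()).casefold()


# --------------------------------------------------------------------------
# dictionaries
# --------------------------------------------------------------------------


@dataclass
class MedDRADictionary:
    """PT → SOC mapping under the primary-SOC convention.

    Each preferred term maps to exactly one system organ class; lookup is
    case-insensitive after whitespace normalization.  The packaged toy
    dictionary stands in for the licensed MedDRA terminology.
    """

    entries: dict[str, str]
    _index: dict[str, str] = field(init=False, repr=False)
    _unmapped_seen: set[str] = field(init=False, repr=False, default_factory=set)

    def __post_init__(self) -> None:
        self._index = {}
        for pt, soc in self.entries.items():
            key = _norm_key(pt)
            if key in self._index and self._index[key] != soc:
                raise ValueError(f"PT {pt!r} maps to multiple SOCs")
            self._index[key] = soc

    @classmethod
    def from_csv(cls, path: str | Path) -> "MedDRADictionary":
        df = pd.read_csv(path, dtype=str)
        if not {"pt", "soc"} <= set(df.columns):
            raise ValueError(f"{path}: dictionary CSV needs columns pt,soc")
        return cls(dict(zip(df["pt"], df["soc"])))

    def soc_of(self, pt: str) -> str:
        soc = self._index.get(_norm_key(pt))
        if soc is None:
            if pt not in self._unmapped_seen:
                self._unmapped_seen.add(pt)
                logger.warning("PT %r not in dictionary; mapped to %s", pt, UNMAPPED)
            return UNMAPPED
        return soc


def map_pt_to_soc(dictionary: MedDRADictionary, pt: str) -> str:
    """Return the unique SOC for a PT, or the ``UNMAPPED`` sentinel."""
    return dictionary.soc_of(pt)


@dataclass
class SynonymTable:
    """Raw drug string → canonical ingredient name.

    A lightweight stand-in for NLP-based trade-name standardization:
    matching is exact after case folding and whitespace normalization,
    unmatched strings pass through unchanged (logged once each).
    """

    entries: dict[str, str]
    _index: dict[str, str] = field(init=False, repr=False)
    _missed: set[str] = field(init=False, repr=False, default_factory=set)

    def __post_init__(self) -> None:
        self._index = {_norm_key(raw): canon for raw, canon in self.entries.items()}

    @classmethod
    def from_csv(cls, path: str | Path) -> "SynonymTable":
        df = pd.read_csv(path, dtype=str)
        if not {"raw", "canonical"} <= set(df.columns):
            raise ValueError(f"{path}: synonym CSV needs columns raw,canonical")
        return cls(dict(zip(df["raw"], df["canonical"])))

    def canonical(self, raw: str) -> str:
        hit = self._index.get(_norm_key(raw))
        if hit is None:
            if raw not in self._missed:
                self._missed.add(raw)
                logger.info("drug name %r has no synonym entry; kept as-is", raw)
            return raw
        return hit


def standardize_drug_names(
    reports: Sequence[SafetyReport], synonyms: SynonymTable
) -> list[SafetyReport]:
    """Replace every drug name with its canonical form where matched."""
    out = []
    for r in reports:
        drugs = [
            DrugEntry(
                name=synonyms.canonical(d.name),
                role=d.role,
                route=d.route,
                indication_pt=d.indication_pt,
                therapy_start=d.therapy_start,
            )
            for d in r.drugs
        ]
        out.append(r.copy(drugs=drugs))
    return out


# --------------------------------------------------------------------------
# reading
# --------------------------------------------------------------------------


def read_reports(
    paths: Sequence[str | Path] | str | Path, dialect: str = "normalized-csv"
) -> list[SafetyReport]:
    """Parse a report database into :class:`SafetyReport` records.

    ``paths`` may be a directory containing the dialect's files or an
    explicit list of file paths.  One report is produced per primary id;
    reports without any reaction are dropped (count logged) because every
    downstream count is conditioned on at least one adverse event.
    """
    files = _resolve_paths(paths, dialect)
    if dialect == "faers-ascii":
        return _read_faers_ascii(files)
    if dialect == "normalized-csv":
        return _read_normalized(files)
    raise ValueError(f"unknown dialect {dialect!r}")


def _resolve_paths(paths, dialect) -> dict[str, Path]:
    if isinstance(paths, (str, Path)):
        root = Path(paths)
        if root.is_dir():
            paths = sorted(root.iterdir())
        else:
            paths = [root]
    files: dict[str, Path] = {}
    if dialect == "faers-ascii":
        for p in map(Path, paths):
            stem = p.name.upper()
            for tag in _FAERS_FILES:
                if stem.startswith(tag):
                    files[tag] = p
        for tag in _MANDATORY:
            if tag not in files:
                raise FileNotFoundError(f"mandatory FAERS file missing: {tag}")
    else:
        for p in map(Path, paths):
            for tag in ("reports", "drugs", "reactions"):
                if p.name.startswith(tag):
                    files[tag] = p
        for tag in ("reports", "reactions"):
            if tag not in files:
                raise FileNotFoundError(f"mandatory file missing: {tag}.csv")
    for p in files.values():
        if not p.exists():
            raise FileNotFoundError(str(p))
    return files


def _read_table(path: Path, sep: str) -> pd.DataFrame:
    bad: list[int] = []

    def on_bad(row):  # pragma: no cover - exercised only on corrupt input
        bad.append(1)
        return None

    try:
        df = pd.read_csv(
            path,
            sep=sep,
            dtype=str,
            keep_default_na=False,
            engine="python",
            on_bad_lines=on_bad,
        )
    except Exception as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    if df.columns.size == 1 and sep not in df.columns[0] and sep == "$":
        raise ValueError(f"{path}: header line 1 not '$'-delimited")
    if bad:
        logger.warning("%s: skipped %d unparseable rows", path.name, len(bad))
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: header line 1 missing columns {missing}")


def _opt(row, col) -> Optional[str]:
    v = row.get(col, "")
    v = str(v).strip()
    return v or None


def _read_faers_ascii(files: dict[str, Path]) -> list[SafetyReport]:
    demo = _read_table(files["DEMO"], "$")
    _require_columns(demo, ["primaryid", "caseid", "caseversion", "fda_dt"], files["DEMO"])
    reac = _read_table(files["REAC"], "$")
    if reac.empty:
        raise ValueError(f"{files['REAC']}: REAC file has no reaction rows")
    _require_columns(reac, ["primaryid", "pt"], files["REAC"])

    drug = _read_table(files["DRUG"], "$") if "DRUG" in files else pd.DataFrame()
    indi = _read_table(files["INDI"], "$") if "INDI" in files else pd.DataFrame()
    outc = _read_table(files["OUTC"], "$") if "OUTC" in files else pd.DataFrame()
    ther = _read_table(files["THER"], "$") if "THER" in files else pd.DataFrame()

    reac_by_id: dict[str, list[Reaction]] = {}
    for row in reac.to_dict("records"):
        pt = str(row.get("pt", "")).strip()
        if not pt:
            continue
        reac_by_id.setdefault(str(row["primaryid"]), []).append(
            Reaction(pt=pt, event_date=parse_event_date(row.get("event_dt")))
        )

    indi_by_seq: dict[tuple[str, str], str] = {}
    if not indi.empty:
        seq_col = "indi_drug_seq" if "indi_drug_seq" in indi.columns else "drug_seq"
        for row in indi.to_dict("records"):
            indi_by_seq[(str(row["primaryid"]), str(row.get(seq_col, "")))] = str(
                row.get("indi_pt", "")
            ).strip()

    ther_by_seq: dict[tuple[str, str], Optional[dt.date]] = {}
    if not ther.empty:
        seq_col = "dsg_drug_seq" if "dsg_drug_seq" in ther.columns else "drug_seq"
        for row in ther.to_dict("records"):
            ther_by_seq[(str(row["primaryid"]), str(row.get(seq_col, "")))] = parse_event_date(
                row.get("start_dt")
            )

    drugs_by_id: dict[str, list[DrugEntry]] = {}
    if not drug.empty:
        _require_columns(drug, ["primaryid", "drugname"], files["DRUG"])
        for row in drug.to_dict("records"):
            pid = str(row["primaryid"])
            seq = str(row.get("drug_seq", ""))
            drugs_by_id.setdefault(pid, []).append(
                DrugEntry(
                    name=str(row.get("drugname", "")).strip(),
                    role=_ROLE_CODES.get(str(row.get("role_cod", "")).strip().upper(), SUSPECT),
                    route=_opt(row, "route"),
                    indication_pt=indi_by_seq.get((pid, seq)) or None,
                    therapy_start=ther_by_seq.get((pid, seq)),
                )
            )

    outc_by_id: dict[str, set[str]] = {}
    if not outc.empty:
        for row in outc.to_dict("records"):
            code = str(row.get("outc_cod", "")).strip().upper()
            if code:
                outc_by_id.setdefault(str(row["primaryid"]), set()).add(code)

    reports: list[SafetyReport] = []
    dropped = 0
    for row in demo.to_dict("records"):
        pid = str(row["primaryid"])
        reactions = reac_by_id.get(pid, [])
        if not reactions:
            dropped += 1
            continue
        receipt, year = parse_faers_date(row.get("fda_dt"))
        age = _opt(row, "age")
        try:
            age_years = float(age) if age is not None else None
        except ValueError:
            age_years = None
        reports.append(
            SafetyReport(
                case_id=str(row.get("caseid", pid)),
                case_version=int(float(row.get("caseversion") or 1)),
                receipt_date=receipt,
                report_year=year,
                drugs=drugs_by_id.get(pid, []),
                reactions=reactions,
                sex=_SEX_CODES.get(str(row.get("sex", "")).strip().upper(), "unspecified"),
                age_years=age_years,
                country=_opt(row, "occr_country"),
                reporter=_OCCP_CODES.get(
                    str(row.get("occp_cod", "")).strip().upper(), "unspecified"
                ),
                outcomes=frozenset(outc_by_id.get(pid, set())),
            )
        )
    if dropped:
        logger.warning("dropped %d DEMO rows without any REAC row", dropped)
    return reports


def _read_normalized(files: dict[str, Path]) -> list[SafetyReport]:
    rep = _read_table(files["reports"], ",")
    _require_columns(rep, ["case_id", "case_version"], files["reports"])
    reac = _read_table(files["reactions"], ",")
    if reac.empty:
        raise ValueError(f"{files['reactions']}: reactions file has no rows")
    drugs = _read_table(files["drugs"], ",") if "drugs" in files else pd.DataFrame()

    def key(row) -> tuple[str, int]:
        return (str(row["case_id"]), int(float(row["case_version"])))

    reac_by: dict[tuple, list[Reaction]] = {}
    for row in reac.to_dict("records"):
        reac_by.setdefault(key(row), []).append(
            Reaction(pt=str(row["pt"]), event_date=parse_event_date(row.get("event_date")))
        )
    drugs_by: dict[tuple, list[DrugEntry]] = {}
    for row in drugs.to_dict("records") if not drugs.empty else []:
        drugs_by.setdefault(key(row), []).append(
            DrugEntry(
                name=str(row["name"]),
                role=str(row.get("role") or SUSPECT),
                route=_opt(row, "route"),
                indication_pt=_opt(row, "indication_pt"),
                therapy_start=parse_event_date(row.get("therapy_start")),
            )
        )

    reports: list[SafetyReport] = []
    dropped = 0
    for row in rep.to_dict("records"):
        k = key(row)
        reactions = reac_by.get(k, [])
        if not reactions:
            dropped += 1
            continue
        receipt, year = parse_faers_date(row.get("receipt_date"))
        ystr = _opt(row, "report_year")
        age = _opt(row, "age_years")
        outcomes = frozenset(c for c in str(row.get("outcomes", "")).split(";") if c)
        reports.append(
            SafetyReport(
                case_id=k[0],
                case_version=k[1],
                receipt_date=receipt,
                report_year=int(float(ystr)) if ystr else year,
                drugs=drugs_by.get(k, []),
                reactions=reactions,
                sex=_opt(row, "sex") or "unspecified",
                age_years=float(age) if age else None,
                country=_opt(row, "country"),
                reporter=_opt(row, "reporter") or "unspecified",
                outcomes=outcomes,
            )
        )
    if dropped:
        logger.warning("dropped %d report rows without any reaction row", dropped)
    return reports


# --------------------------------------------------------------------------
# writing (normalized-csv and faers-ascii dialects)
# --------------------------------------------------------------------------


def _date_str(d: Optional[dt.date]) -> str:
    return d.strftime("%Y%m%d") if d else ""


def write_reports(
    reports: Sequence[SafetyReport], out_dir: str | Path, dialect: str = "normalized-csv"
) -> dict[str, Path]:
    """Serialize reports to ``out_dir`` in the given dialect; returns the files written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if dialect == "normalized-csv":
        return _write_normalized(reports, out)
    if dialect == "faers-ascii":
        return _write_faers_ascii(reports, out)
    raise ValueError(f"unknown dialect {dialect!r}")


def _write_normalized(reports: Sequence[SafetyReport], out: Path) -> dict[str, Path]:
    paths = {t: out / f"{t}.csv" for t in ("reports", "drugs", "reactions")}
    with open(paths["reports"], "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(
            [
                "case_id",
                "case_version",
                "receipt_date",
                "report_year",
                "sex",
                "age_years",
                "country",
                "reporter",
                "outcomes",
            ]
        )
        for r in reports:
            w.writerow(
                [
                    r.case_id,
                    r.case_version,
                    _date_str(r.receipt_date),
                    r.report_year if r.report_year is not None else "",
                    r.sex,
                    r.age_years if r.age_years is not None else "",
                    r.country or "",
                    r.reporter,
                    ";".join(sorted(r.outcomes)),
                ]
            )
    with open(paths["drugs"], "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(
            ["case_id", "case_version", "name", "role", "route", "indication_pt", "therapy_start"]
        )
        for r in reports:
            for d in r.drugs:
                w.writerow(
                    [
                        r.case_id,
                        r.case_version,
                        d.name,
                        d.role,
                        d.route or "",
                        d.indication_pt or "",
                        _date_str(d.therapy_start),
                    ]
                )
    with open(paths["reactions"], "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["case_id", "case_version", "pt", "event_date"])
        for r in reports:
            for rx in r.reactions:
                w.writerow([r.case_id, r.case_version, rx.pt, _date_str(rx.event_date)])
    return paths


_SEX_OUT = {"female": "F", "male": "M", "unspecified": ""}
_OCCP_OUT = {
    "consumer": "CN",
    "pharmacist": "PH",
    "physician": "MD",
    "other-health-professional": "OT",
    "unspecified": "",
}


def _write_faers_ascii(reports: Sequence[SafetyReport], out: Path) -> dict[str, Path]:
    paths = {t: out / f"{t}.txt" for t in _FAERS_FILES}
    handles = {t: open(p, "w", newline="") for t, p in paths.items()}
    try:
        wr = {t: csv.writer(h, delimiter="$") for t, h in handles.items()}
        wr["DEMO"].writerow(
            ["primaryid", "caseid", "caseversion", "fda_dt", "sex", "age", "age_cod",
             "occr_country", "occp_cod"]
        )
        wr["DRUG"].writerow(["primaryid", "drug_seq", "drugname", "role_cod", "route"])
        wr["REAC"].writerow(["primaryid", "pt", "event_dt"])
        wr["INDI"].writerow(["primaryid", "indi_drug_seq", "indi_pt"])
        wr["OUTC"].writerow(["primaryid", "outc_cod"])
        wr["THER"].writerow(["primaryid", "dsg_drug_seq", "start_dt"])
        for r in reports:
            pid = f"{r.case_id}-{r.case_version}"
            wr["DEMO"].writerow(
                [
                    pid,
                    r.case_id,
                    r.case_version,
                    _date_str(r.receipt_date) or (r.report_year or ""),
                    _SEX_OUT.get(r.sex, ""),
                    r.age_years if r.age_years is not None else "",
                    "YR" if r.age_years is not None else "",
                    r.country or "",
                    _OCCP_OUT.get(r.reporter, ""),
                ]
            )
            for seq, d in enumerate(r.drugs, start=1):
                wr["DRUG"].writerow(
                    [pid, seq, d.name, "PS" if d.role == SUSPECT else "C", d.route or ""]
                )
                if d.indication_pt:
                    wr["INDI"].writerow([pid, seq, d.indication_pt])
                if d.therapy_start:
                    wr["THER"].writerow([pid, seq, _date_str(d.therapy_start)])
            for rx in r.reactions:
                wr["REAC"].writerow([pid, rx.pt, _date_str(rx.event_date)])
            for code in sorted(r.outcomes):
                wr["OUTC"].writerow([pid, code])
    finally:
        for h in handles.values():
            h.close()
    return paths


# --------------------------------------------------------------------------
# deduplication
# --------------------------------------------------------------------------


def deduplicate(reports: Sequence[SafetyReport]) -> list[SafetyReport]:
    """Collapse duplicate reports; idempotent.

    Stage 1 keeps exactly one report per ``case_id``: the highest
    ``case_version``, ties broken by latest receipt date, then by first
    position in input order.  Stage 2 collapses reports with *distinct*
    case ids but identical (sex, age, country, drug-name set, PT set,
    event-date multiset), keeping the earliest received — an exact-match
    stand-in for manual cross-submission verification.  Because absent
    fields cannot verify anything, stage 2 only considers reports whose
    verification fields are complete (sex specified, age and country
    present, at least one event date); otherwise distinct cases sharing
    a "not specified" profile would be merged wholesale.  Output
    preserves the input order of the survivors.
    """
    best: dict[str, tuple[tuple, int]] = {}
    for idx, r in enumerate(reports):
        rank = (r.case_version, r.receipt_date or dt.date.min, -idx)
        cur = best.get(r.case_id)
        if cur is None or rank > cur[0]:
            best[r.case_id] = (rank, idx)
    survivors = sorted(idx for _, idx in best.values())

    def field_key(r: SafetyReport) -> tuple:
        return (
            r.sex,
            r.age_years,
            r.country,
            frozenset(d.name for d in r.drugs),
            r.pt_set(),
            tuple(sorted(_date_str(rx.event_date) for rx in r.reactions)),
        )

    def verifiable(r: SafetyReport) -> bool:
        return (
            r.sex != "unspecified"
            and r.age_years is not None
            and r.country is not None
            and any(rx.event_date is not None for rx in r.reactions)
        )

    kept: dict[tuple, tuple[tuple, int]] = {}
    unverifiable: list[int] = []
    for idx in survivors:
        r = reports[idx]
        if not verifiable(r):
            unverifiable.append(idx)
            continue
        rank = (r.receipt_date or dt.date.max, idx)  # earliest received wins
        k = field_key(r)
        cur = kept.get(k)
        if cur is None or rank < cur[0]:
            kept[k] = (rank, idx)
    final = sorted(unverifiable + [idx for _, idx in kept.values()])
    n_dropped = len(reports) - len(final)
    if n_dropped:
        logger.info("deduplicate: removed %d of %d reports", n_dropped, len(reports))
    return [reports[i] for i in final]


# --------------------------------------------------------------------------
# cohort extraction
# --------------------------------------------------------------------------


def filter_cohort(
    reports: Sequence[SafetyReport],
    drug: str,
    indication_pts: Iterable[str],
    window: tuple[str | Quarter, str | Quarter],
) -> tuple[list[SafetyReport], list[SafetyReport]]:
    """Split in-window reports into (cohort, background).

    A report joins the cohort when any *suspect* drug entry carries the
    target drug (case-insensitive on the standardized name) with an
    indication in ``indication_pts``; every other in-window report is
    background.  Reports whose receipt quarter is unknown or outside the
    window appear in neither output.
    """
    start, end = parse_quarter(window[0]), parse_quarter(window[1])
    if start > end:
        raise ValueError(f"window start {window[0]!r} after end {window[1]!r}")
    drug_key = _norm_key(drug)
    indi_keys = {_norm_key(i) for i in indication_pts}
    cohort: list[SafetyReport] = []
    background: list[SafetyReport] = []
    for r in reports:
        if not in_window(r, start, end):
            continue
        hit = any(
            _norm_key(d.name) == drug_key
            and d.indication_pt is not None
            and _norm_key(d.indication_pt) in indi_keys
            for d in r.suspect_drugs()
        )
        (cohort if hit else background).append(r)
    return cohort, background
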