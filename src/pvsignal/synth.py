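"""Synthetic FAERS-like report databases with known ground truth.

The generator emulates the statistical structure a disproportionality
pipeline relies on — one-to-many report→PT multiplicity, case-version
duplicates, suspect drugs with indications, demographic fields with
"not specified" missingness, outcome codes including death, and
therapy-start/event dates for time-to-onset — while planting known
reporting-rate-ratio elevations for chosen PTs in the target cohort.

Per-PT occurrence is independent Bernoulli: report r mentions PT p with
probability ``rate_p * (rr_p if r is in the cohort and p is planted)``;
reports that would end up with no reaction are redrawn, mirroring the
ingestion invariant.  Each field group (PTs, demographics, dates,
duplication, outcomes, drugs) draws from its own stream split off the
master seed, so adding a field never perturbs the other groups' draws.

Deliberately NOT modelled: stimulated reporting, the Weber effect, drug
interactions, secular trends in PT coding — synthetic results validate
the machinery and its statistics, not real-world reporting biases.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as fio
from .contingency import build_tables, observed_expected_all_pairs
from .dispro import compute_result, fit_mgps_prior
from .reports import DrugEntry, Reaction, SafetyReport, parse_quarter
from .resources import load_default_synonyms
from .signals import DEFAULT_THRESHOLDS, SignalThresholds, evaluate_signal

__all__ = ["PTSpec", "SynthConfig", "default_catalog", "generate", "end_to_end_recovery"]


@dataclass(frozen=True)
class PTSpec:
    pt: str
    soc: str
    rate: float  # per-report background occurrence probability


# Background catalog: ~50 PTs over 18 SOCs with rates spanning rare
# (0.002/report) to very common (0.09/report), loosely shaped like the
# event mix of a biologic in an inflammatory-bowel-disease population.
_CATALOG: tuple[tuple[str, str, float], ...] = (
    ("Abscess", "Infections and infestations", 0.010),
    ("Anal abscess", "Infections and infestations", 0.003),
    ("Lower respiratory tract infection", "Infections and infestations", 0.012),
    ("Upper respiratory tract infection", "Infections and infestations", 0.025),
    ("Nasopharyngitis", "Infections and infestations", 0.030),
    ("Pneumonia", "Infections and infestations", 0.015),
    ("Urinary tract infection", "Infections and infestations", 0.012),
    ("Kidney infection", "Infections and infestations", 0.005),
    ("Cellulitis", "Infections and infestations", 0.006),
    ("Gastrointestinal infection", "Infections and infestations", 0.004),
    ("Clostridium difficile infection", "Infections and infestations", 0.008),
    ("Postoperative wound infection", "Infections and infestations", 0.003),
    ("Abdominal pain", "Gastrointestinal disorders", 0.040),
    ("Diarrhoea", "Gastrointestinal disorders", 0.050),
    ("Nausea", "Gastrointestinal disorders", 0.060),
    ("Vomiting", "Gastrointestinal disorders", 0.030),
    ("Intestinal obstruction", "Gastrointestinal disorders", 0.006),
    ("Haematochezia", "Gastrointestinal disorders", 0.005),
    ("Fistula", "Gastrointestinal disorders", 0.003),
    ("Frequent bowel movements", "Gastrointestinal disorders", 0.004),
    ("Intestinal stenosis", "Gastrointestinal disorders", 0.002),
    ("Off label use", "Injury, poisoning and procedural complications", 0.080),
    ("Product dose omission issue", "Injury, poisoning and procedural complications", 0.040),
    ("Accidental exposure to product", "Injury, poisoning and procedural complications", 0.010),
    ("Infusion related reaction", "Injury, poisoning and procedural complications", 0.012),
    ("Fatigue", "General disorders and administration site conditions", 0.050),
    ("Pyrexia", "General disorders and administration site conditions", 0.030),
    ("Injection site pain", "General disorders and administration site conditions", 0.040),
    ("Drug ineffective", "General disorders and administration site conditions", 0.090),
    ("Condition aggravated", "General disorders and administration site conditions", 0.030),
    ("Headache", "Nervous system disorders", 0.050),
    ("Dizziness", "Nervous system disorders", 0.030),
    ("Migraine", "Nervous system disorders", 0.008),
    ("Rash", "Skin and subcutaneous tissue disorders", 0.040),
    ("Pruritus", "Skin and subcutaneous tissue disorders", 0.030),
    ("Arthralgia", "Musculoskeletal and connective tissue disorders", 0.035),
    ("Back pain", "Musculoskeletal and connective tissue disorders", 0.020),
    ("Myocardial infarction", "Cardiac disorders", 0.006),
    ("Cardiac failure", "Cardiac disorders", 0.005),
    ("Palpitations", "Cardiac disorders", 0.008),
    ("Cholelithiasis", "Hepatobiliary disorders", 0.004),
    ("Cholangitis", "Hepatobiliary disorders", 0.002),
    ("Hepatic function abnormal", "Hepatobiliary disorders", 0.003),
    ("Skin cancer", "Neoplasms benign, malignant and unspecified (incl cysts and polyps)", 0.004),
    ("Basal cell carcinoma", "Neoplasms benign, malignant and unspecified (incl cysts and polyps)", 0.003),
    ("Lymphoma", "Neoplasms benign, malignant and unspecified (incl cysts and polyps)", 0.002),
    ("Cough", "Respiratory, thoracic and mediastinal disorders", 0.025),
    ("Dyspnoea", "Respiratory, thoracic and mediastinal disorders", 0.020),
    ("Drug level decreased", "Investigations", 0.005),
    ("Weight decreased", "Investigations", 0.015),
    ("Anxiety", "Psychiatric disorders", 0.015),
    ("Depression", "Psychiatric disorders", 0.015),
    ("Hypertension", "Vascular disorders", 0.015),
    ("Vision blurred", "Eye disorders", 0.008),
    ("Anaemia", "Blood and lymphatic system disorders", 0.012),
    ("Nephrolithiasis", "Renal and urinary disorders", 0.005),
    ("Hypersensitivity", "Immune system disorders", 0.010),
    ("Decreased appetite", "Metabolism and nutrition disorders", 0.012),
)

# Background suspect drugs with a plausible indication each; a small
# fraction of background reports instead carries the target drug under a
# non-target indication, exercising the indication-restriction filter.
_BG_DRUGS: tuple[tuple[str, str], ...] = (
    ("REMICADE", "Crohn's disease"),
    ("HUMIRA", "Rheumatoid arthritis"),
    ("ENTYVIO", "Ulcerative colitis"),
    ("METHOTREXATE", "Rheumatoid arthritis"),
    ("PREDNISONE", "Ulcerative colitis"),
    ("AZATHIOPRINE", "Crohn's disease"),
    ("MESALAMINE", "Ulcerative colitis"),
    ("IBUPROFEN", "Back pain"),
    ("LISINOPRIL", "Hypertension"),
    ("METFORMIN", "Decreased appetite"),
)

_COUNTRIES = ("US", "CA", "GB", "AU", "FR", "DE", "JP")
_COUNTRY_P = (0.55, 0.22, 0.08, 0.02, 0.05, 0.05, 0.03)
_REPORTERS = ("consumer", "pharmacist", "physician", "other-health-professional")
_REPORTER_P = (0.42, 0.35, 0.15, 0.08)
_ROUTES = ("subcutaneous", "intravenous")
_ROUTE_P = (0.855, 0.145)


def default_catalog() -> list[PTSpec]:
    return [PTSpec(*row) for row in _CATALOG]


def _default_missing_rates() -> dict[str, float]:
    # Shaped like the "not specified" shares of a real cohort table:
    # age missing ~37%, sex ~7%, therapy start missing often enough that
    # most reports have no classifiable time-to-onset.
    return {
        "sex": 0.07,
        "age": 0.37,
        "country": 0.05,
        "reporter": 0.01,
        "route": 0.06,
        "event_date": 0.25,
        "therapy_start": 0.60,
    }


def _default_death_rates() -> dict[str, float]:
    return {
        "Cardiac disorders": 0.075,
        "Neoplasms benign, malignant and unspecified (incl cysts and polyps)": 0.055,
        "Hepatobiliary disorders": 0.022,
        "Infections and infestations": 0.020,
        "*": 0.008,
    }


@dataclass
class SynthConfig:
    """Generator parameters; the defaults define the reference study conditions.

    ``planted`` lists (pt, rate_ratio) pairs whose cohort reporting rate
    is the background rate multiplied by the ratio; everything else is
    null (ratio 1).  ``seed`` fixes every stream, so identical configs
    serialize byte-identically.
    """

    n_cohort: int = 5000
    n_background: int = 100_000
    pt_catalog: list[PTSpec] = dc_field(default_factory=default_catalog)
    planted: list[tuple[str, float]] = dc_field(default_factory=list)
    duplicate_rate: float = 0.10
    missing_rates: dict[str, float] = dc_field(default_factory=_default_missing_rates)
    death_rate_by_soc: dict[str, float] = dc_field(default_factory=_default_death_rates)
    tto_lognormal: tuple[float, float] = (math.log(80.0), 2.0)  # median 80 days
    seed: int = 0
    drug: str = "ustekinumab"
    indication_pt: str = "Crohn's disease"
    window: tuple[str, str] = ("2016Q4", "2023Q4")
    target_offlabel_frac: float = 0.03  # background share with target drug, other indication

    def validate(self) -> None:
        if self.n_cohort <= 0:
            raise ValueError("n_cohort must be positive")
        if self.n_background <= 0:
            raise ValueError("n_background must be positive")
        if not 0 <= self.duplicate_rate < 1:
            raise ValueError("duplicate_rate must lie in [0, 1)")
        catalog_pts = {p.pt for p in self.pt_catalog}
        for spec in self.pt_catalog:
            if not 0 < spec.rate < 1:
                raise ValueError(f"pt_catalog rate out of (0,1) for {spec.pt!r}")
        for pt, rr in self.planted:
            if rr <= 0:
                raise ValueError(f"planted rate_ratio must be positive for {pt!r}")
            if pt not in catalog_pts:
                raise ValueError(f"planted PT {pt!r} not in pt_catalog")
        for name, rate in self.missing_rates.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"missing_rates[{name!r}] out of [0,1]")
        for soc, rate in self.death_rate_by_soc.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"death_rate_by_soc[{soc!r}] out of [0,1]")
        parse_quarter(self.window[0]), parse_quarter(self.window[1])


def _window_dates(config: SynthConfig) -> tuple[dt.date, int]:
    (y0, q0) = parse_quarter(config.window[0])
    (y1, q1) = parse_quarter(config.window[1])
    start = dt.date(y0, 3 * (q0 - 1) + 1, 1)
    if q1 == 4:
        end = dt.date(y1 + 1, 1, 1) - dt.timedelta(days=1)
    else:
        end = dt.date(y1, 3 * q1 + 1, 1) - dt.timedelta(days=1)
    return start, (end - start).days


def generate(config: SynthConfig) -> tuple[list[SafetyReport], set[str]]:
    """Draw a full report database; returns (reports, planted PT set).

    The emitted list contains ``n_cohort + n_background`` distinct cases
    plus ``round(duplicate_rate * n)`` re-submissions (version 2 of an
    existing case), in stable order: originals first, duplicates after.
    """
    config.validate()
    n_cohort, n_bg = config.n_cohort, config.n_background
    n = n_cohort + n_bg
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_pts = np.random.default_rng(streams[0])
    rng_demo = np.random.default_rng(streams[1])
    rng_dates = np.random.default_rng(streams[2])
    rng_dup = np.random.default_rng(streams[3])
    rng_outc = np.random.default_rng(streams[4])
    rng_drug = np.random.default_rng(streams[5])

    pts = [s.pt for s in config.pt_catalog]
    socs = [s.soc for s in config.pt_catalog]
    base_rates = np.array([s.rate for s in config.pt_catalog])
    planted_map = dict(config.planted)
    cohort_rates = np.minimum(
        base_rates * np.array([planted_map.get(p, 1.0) for p in pts]), 0.95
    )

    # per-report PT incidence; empty rows are redrawn so every report has
    # at least one reaction (the ingestion invariant)
    mat = np.empty((n, len(pts)), dtype=bool)
    mat[:n_cohort] = rng_pts.random((n_cohort, len(pts))) < cohort_rates
    mat[n_cohort:] = rng_pts.random((n_bg, len(pts))) < base_rates
    for _ in range(200):
        empty = ~mat.any(axis=1)
        if not empty.any():
            break
        k = int(empty.sum())
        rows_rates = np.where(np.nonzero(empty)[0][:, None] < n_cohort, cohort_rates, base_rates)
        mat[empty] = rng_pts.random((k, len(pts))) < rows_rates
    else:  # pragma: no cover - only reachable with pathologically tiny rates
        for i in np.nonzero(~mat.any(axis=1))[0]:
            mat[i, rng_pts.choice(len(pts), p=base_rates / base_rates.sum())] = True

    # dates: receipt uniform over the window; event = receipt - lag;
    # therapy start = event - TTO (log-normal days)
    win_start, span = _window_dates(config)
    receipt_off = rng_dates.integers(0, span + 1, size=n)
    lag = rng_dates.exponential(30.0, size=n).astype(int)
    mu, sigma = config.tto_lognormal
    # heavy upper tail clipped so therapy start stays on the calendar
    tto = np.minimum(rng_dates.lognormal(mu, sigma, size=n), 36500.0).astype(int)
    miss = config.missing_rates
    event_missing = rng_dates.random(n) < miss.get("event_date", 0.0)
    ther_missing = rng_dates.random(n) < miss.get("therapy_start", 0.0)

    # demographics
    sex = rng_demo.choice(["female", "male"], size=n, p=[0.624, 0.376])
    sex_missing = rng_demo.random(n) < miss.get("sex", 0.0)
    age = np.clip(rng_demo.normal(44.0, 16.0, size=n), 1.0, 95.0).round(0)
    age_missing = rng_demo.random(n) < miss.get("age", 0.0)
    country = rng_demo.choice(_COUNTRIES, size=n, p=_COUNTRY_P)
    country_missing = rng_demo.random(n) < miss.get("country", 0.0)
    reporter = rng_demo.choice(_REPORTERS, size=n, p=_REPORTER_P)
    reporter_missing = rng_demo.random(n) < miss.get("reporter", 0.0)
    route = rng_demo.choice(_ROUTES, size=n, p=_ROUTE_P)
    route_missing = rng_demo.random(n) < miss.get("route", 0.0)

    # outcomes: death hazard from the most fatal SOC on the report
    death_default = config.death_rate_by_soc.get("*", 0.0)
    soc_rate = np.array(
        [config.death_rate_by_soc.get(s, death_default) for s in socs]
    )
    p_death = np.where(mat, soc_rate, 0.0).max(axis=1)
    u = rng_outc.random((n, 4))
    has_de = u[:, 0] < p_death
    has_ho = u[:, 1] < 0.25
    has_lt = u[:, 2] < 0.015
    has_ot = u[:, 3] < 0.55

    # drug assignment
    raw_target = rng_drug.choice(["USTEKINUMAB", "STELARA"], size=n, p=[0.7, 0.3])
    bg_drug_idx = rng_drug.integers(0, len(_BG_DRUGS), size=n)
    bg_offlabel = rng_drug.random(n) < config.target_offlabel_frac

    reports: list[SafetyReport] = []
    for i in range(n):
        is_cohort = i < n_cohort
        receipt = win_start + dt.timedelta(days=int(receipt_off[i]))
        event = receipt - dt.timedelta(days=int(lag[i]))
        start = event - dt.timedelta(days=int(tto[i]))
        event_date = None if event_missing[i] else event
        ther_date = None if ther_missing[i] else start
        if is_cohort:
            drug = DrugEntry(
                name=str(raw_target[i]),
                role="suspect",
                route=None if route_missing[i] else str(route[i]),
                indication_pt=config.indication_pt,
                therapy_start=ther_date,
            )
        elif bg_offlabel[i]:
            drug = DrugEntry(
                name=str(raw_target[i]),
                role="suspect",
                route=None if route_missing[i] else str(route[i]),
                indication_pt="Psoriasis",
                therapy_start=ther_date,
            )
        else:
            name, indi = _BG_DRUGS[int(bg_drug_idx[i])]
            drug = DrugEntry(
                name=name,
                role="suspect",
                route=None,
                indication_pt=indi,
                therapy_start=ther_date,
            )
        outcodes = set()
        if has_de[i]:
            outcodes.add("DE")
        if has_ho[i]:
            outcodes.add("HO")
        if has_lt[i]:
            outcodes.add("LT")
        if has_ot[i]:
            outcodes.add("OT")
        reports.append(
            SafetyReport(
                case_id=f"SYN{i:08d}",
                case_version=1,
                receipt_date=receipt,
                report_year=receipt.year,
                drugs=[drug],
                reactions=[
                    Reaction(pt=pts[j], event_date=event_date)
                    for j in np.nonzero(mat[i])[0]
                ],
                sex="unspecified" if sex_missing[i] else str(sex[i]),
                age_years=None if age_missing[i] else float(age[i]),
                country=None if country_missing[i] else str(country[i]),
                reporter="unspecified" if reporter_missing[i] else str(reporter[i]),
                outcomes=frozenset(outcodes),
            )
        )

    n_dup = int(round(config.duplicate_rate * n))
    if n_dup:
        dup_idx = np.sort(rng_dup.choice(n, size=n_dup, replace=False))
        for i in dup_idx:
            r = reports[int(i)]
            reports.append(r.copy(case_version=2))

    return reports, set(planted_map)


def write_database(
    reports: Sequence[SafetyReport], truth: set[str], out_dir: str | Path
) -> None:
    """Write both dialects plus the planted-signal truth table."""
    out = Path(out_dir)
    fio.write_reports(reports, out / "normalized", dialect="normalized-csv")
    fio.write_reports(reports, out / "faers", dialect="faers-ascii")
    pd.DataFrame({"pt": sorted(truth)}).to_csv(out / "truth.csv", index=False)


def end_to_end_recovery(
    config: SynthConfig,
    thresholds: SignalThresholds = DEFAULT_THRESHOLDS,
    a_min_fp: int = 3,
) -> dict[str, object]:
    """Generate a database, run the full pipeline, score against the truth.

    Returns sensitivity on planted PTs (``None`` when nothing was
    planted), the false-positive rate among unplanted PTs with at least
    ``a_min_fp`` cohort reports, the evaluated per-PT results, and the
    filter-step counts.
    """
    reports, truth = generate(config)
    reports = fio.standardize_drug_names(reports, load_default_synonyms())
    deduped = fio.deduplicate(reports)
    cohort, background = fio.filter_cohort(
        deduped, config.drug, {config.indication_pt}, config.window
    )
    tables = build_tables(cohort, background, level="PT")
    a_all, e_all = observed_expected_all_pairs(cohort + background)
    prior = fit_mgps_prior(a_all, e_all, seed=config.seed)
    results = [
        evaluate_signal(compute_result(ev, t, prior), thresholds)
        for ev, t in tables.items()
    ]
    detected = {r.event for r in results if r.signal}
    if truth:
        sensitivity = len(detected & truth) / len(truth)
    else:
        sensitivity = None
    null_eval = [r for r in results if r.event not in truth and r.n_reports >= a_min_fp]
    fp_rate = (
        sum(r.signal for r in null_eval) / len(null_eval) if null_eval else 0.0
    )
    return {
        "sensitivity": sensitivity,
        "fp_rate": fp_rate,
        "n_null_evaluated": len(null_eval),
        "detected": detected,
        "truth": truth,
        "results": results,
        "prior": prior,
        "counts": {
            "generated": len(reports),
            "deduplicated": len(deduped),
            "cohort": len(cohort),
            "background": len(background),
        },
    }
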