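"""End-to-end orchestration: config → filtered cohort → signal tables.

The flow mirrors standard FAERS practice: ingest (or simulate) reports,
standardize drug names, deduplicate cases, restrict to the target drug +
indication + quarter window, build PT- and SOC-level four-grid tables,
fit the empirical-Bayes prior on the whole database, compute all four
statistics, apply the combined signal criterion, and emit descriptive
tables.  All outputs are deterministic functions of the config (every
random stream is seeded from it); files are written to a temporary
directory and moved into place only on success.
"""

from __future__ import annotations

import logging
import math
import os
import shutil
import tempfile
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import io as fio
from .contingency import build_tables, observed_expected_all_pairs, tables_to_frame
from .descriptives import (
    death_proportion_by_soc,
    summarize_demographics,
    summarize_tto,
    yearly_counts,
)
from .dispro import compute_result, fit_mgps_prior
from .resources import load_default_dictionary, load_default_synonyms
from .signals import SignalThresholds, evaluate_signal, rank_signals
from .synth import PTSpec, SynthConfig, generate, write_database

logger = logging.getLogger(__name__)

__all__ = ["load_config", "validate_config", "run_pipeline"]

_THRESHOLD_KEYS = {
    "a_min", "ror_min", "ror_lo_min", "prr_min", "prr_lo_min", "ic025_min", "ebgm05_min",
}


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def validate_config(cfg: dict[str, Any]) -> None:
    """Reject invalid configs before any I/O happens."""
    for key in ("drug", "indication_pts", "window", "input"):
        if key not in cfg:
            raise ValueError(f"config missing required key {key!r}")
    win = cfg["window"]
    from .reports import parse_quarter

    start, end = parse_quarter(win["start"]), parse_quarter(win["end"])
    if start > end:
        raise ValueError(f"window start {win['start']!r} after end {win['end']!r}")
    inp = cfg["input"]
    if ("simulate" in inp) == ("paths" in inp):
        raise ValueError("input must contain exactly one of 'simulate' or 'paths'")
    if "paths" in inp and inp.get("dialect") not in ("faers-ascii", "normalized-csv"):
        raise ValueError("input.dialect must be 'faers-ascii' or 'normalized-csv'")
    extra = set(cfg.get("thresholds", {})) - _THRESHOLD_KEYS
    if extra:
        raise ValueError(f"unknown threshold keys: {sorted(extra)}")
    pctl = cfg.get("ebgm_percentile", 0.05)
    if pctl not in (0.05, 0.025):
        raise ValueError("ebgm_percentile must be 0.05 or 0.025")


def _synth_config(cfg: dict[str, Any], seed: int) -> SynthConfig:
    sim = dict(cfg["input"]["simulate"] or {})
    if "pt_catalog" in sim:
        sim["pt_catalog"] = [PTSpec(*row) for row in sim["pt_catalog"]]
    if "planted" in sim:
        sim["planted"] = [tuple(p) for p in sim["planted"]]
    sim.setdefault("drug", cfg["drug"])
    sim.setdefault("indication_pt", cfg["indication_pts"][0])
    sim.setdefault("window", (cfg["window"]["start"], cfg["window"]["end"]))
    sim["seed"] = seed
    return SynthConfig(**sim)


def _fmt2(x: float) -> str:
    return "" if isinstance(x, float) and math.isnan(x) else f"{x:.2f}"


def _results_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "event": r.event,
                "n_reports": r.n_reports,
                "ror": r.ror, "ror_lo": r.ror_lo, "ror_hi": r.ror_hi,
                "prr": r.prr, "prr_lo": r.prr_lo, "prr_hi": r.prr_hi,
                "ic": r.ic, "ic025": r.ic025,
                "ebgm": r.ebgm, "ebgm05": r.ebgm05,
                "flag_ror": r.flags.get("ror", False),
                "flag_prr": r.flags.get("prr", False),
                "flag_ic": r.flags.get("ic", False),
                "flag_ebgm": r.flags.get("ebgm", False),
                "signal": r.signal,
            }
        )
    return pd.DataFrame(rows)


def _top_frame(ranked) -> pd.DataFrame:
    rows = []
    for r in ranked:
        rows.append(
            {
                "event": r.event,
                "reports": r.n_reports,
                "ROR (95% CI)": f"{_fmt2(r.ror)} ({_fmt2(r.ror_lo)}, {_fmt2(r.ror_hi)})",
                "PRR (95% CI)": f"{_fmt2(r.prr)} ({_fmt2(r.prr_lo)}, {_fmt2(r.prr_hi)})",
                "IC (IC025)": f"{_fmt2(r.ic)} ({_fmt2(r.ic025)})",
                "EBGM (EBGM05)": f"{_fmt2(r.ebgm)} ({_fmt2(r.ebgm05)})",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["event", "reports", "ROR (95% CI)", "PRR (95% CI)",
                 "IC (IC025)", "EBGM (EBGM05)"],
    )


def run_pipeline(
    cfg: dict[str, Any], out_dir: str | Path, seed_override: Optional[int] = None
) -> dict[str, Any]:
    """Execute the full flow; returns the flow counts and key artifacts.

    Outputs written to ``out_dir``: signals.csv, signals_top.csv,
    table1.csv, table4.csv, yearly.csv, soc_tables.csv, flow_counts.csv,
    run.log.  On any failure the partially written temporary directory is
    removed and ``out_dir`` is left untouched.
    """
    validate_config(cfg)
    seed = int(seed_override if seed_override is not None else cfg.get("seed", 0))
    out = Path(out_dir)
    tmp = Path(tempfile.mkdtemp(prefix=".pvsignal-", dir=out.parent if out.parent.exists() else None))

    log_path = tmp / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("pvsignal")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("parameters: drug=%s indications=%s window=%s seed=%d",
                    cfg["drug"], cfg["indication_pts"], cfg["window"], seed)
        dictionary = (
            fio.MedDRADictionary.from_csv(cfg["dictionary"])
            if cfg.get("dictionary")
            else load_default_dictionary()
        )
        synonyms = (
            fio.SynonymTable.from_csv(cfg["synonyms"])
            if cfg.get("synonyms")
            else load_default_synonyms()
        )

        inp = cfg["input"]
        if "simulate" in inp:
            reports, truth = generate(_synth_config(cfg, seed))
            logger.info("simulated %d reports (%d planted PTs)", len(reports), len(truth))
        else:
            reports = fio.read_reports(inp["paths"], dialect=inp["dialect"])
            logger.info("read %d reports", len(reports))

        counts: dict[str, int] = {"extracted": len(reports)}
        reports = fio.standardize_drug_names(reports, synonyms)
        deduped = fio.deduplicate(reports)
        counts["deduplicated"] = len(deduped)
        drug_key = cfg["drug"].casefold()
        counts["drug_matched"] = sum(
            any(d.name.casefold() == drug_key for d in r.suspect_drugs()) for r in deduped
        )
        cohort, background = fio.filter_cohort(
            deduped, cfg["drug"], cfg["indication_pts"],
            (cfg["window"]["start"], cfg["window"]["end"]),
        )
        counts["cohort"] = len(cohort)
        counts["background"] = len(background)
        logger.info("flow counts: %s", counts)

        thresholds = SignalThresholds(**cfg.get("thresholds", {}))
        pctl = float(cfg.get("ebgm_percentile", 0.05))
        pt_tables = build_tables(cohort, background, level="PT")
        soc_tables = build_tables(cohort, background, level="SOC", dictionary=dictionary)
        a_all, e_all = observed_expected_all_pairs(cohort + background)
        prior = fit_mgps_prior(a_all, e_all, seed=seed)
        results = [
            evaluate_signal(compute_result(ev, t, prior, ebgm_percentile=pctl), thresholds)
            for ev, t in pt_tables.items()
        ]
        soc_results = [
            evaluate_signal(compute_result(ev, t, prior, ebgm_percentile=pctl), thresholds)
            for ev, t in soc_tables.items()
        ]
        ranked = rank_signals(results, by=cfg.get("rank_by", "n_reports"),
                              top=int(cfg.get("top", 30)))

        demo = summarize_demographics(cohort)
        tto = summarize_tto(cohort, cfg["drug"])
        table1 = pd.concat([demo["table"], tto["table"]], ignore_index=True)
        summary_rows = pd.DataFrame(
            [
                {"block": "age_summary", "category": "median", "count": "", "pct": demo["age_median"]},
                {"block": "age_summary", "category": "q1", "count": "", "pct": demo["age_q1"]},
                {"block": "age_summary", "category": "q3", "count": "", "pct": demo["age_q3"]},
                {"block": "tto_summary", "category": "median_days", "count": "", "pct": tto["tto_median"]},
                {"block": "tto_summary", "category": "q1_days", "count": "", "pct": tto["tto_q1"]},
                {"block": "tto_summary", "category": "q3_days", "count": "", "pct": tto["tto_q3"]},
            ]
        )
        table1 = pd.concat([table1, summary_rows], ignore_index=True)

        _results_frame(results).to_csv(tmp / "signals.csv", index=False)
        _top_frame(ranked).to_csv(tmp / "signals_top.csv", index=False)
        table1.to_csv(tmp / "table1.csv", index=False)
        death_proportion_by_soc(cohort, dictionary).to_csv(tmp / "table4.csv", index=False)
        yearly_counts(cohort).to_csv(tmp / "yearly.csv", index=False)
        pd.concat(
            [tables_to_frame(pt_tables, "PT"), tables_to_frame(soc_tables, "SOC")],
            ignore_index=True,
        ).to_csv(tmp / "soc_tables.csv", index=False)
        pd.DataFrame([counts]).to_csv(tmp / "flow_counts.csv", index=False)
        logger.info("MGPS prior: %s", prior)
    except Exception:
        root.removeHandler(handler)
        handler.close()
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    root.removeHandler(handler)
    handler.close()

    out.mkdir(parents=True, exist_ok=True)
    for f in sorted(tmp.iterdir()):
        os.replace(f, out / f.name)
    tmp.rmdir()
    return {
        "counts": counts,
        "results": results,
        "soc_results": soc_results,
        "ranked": ranked,
        "prior": prior,
    }


def simulate_to_dir(cfg: dict[str, Any], out_dir: str | Path,
                    seed_override: Optional[int] = None) -> None:
    """Materialize the configured synthetic database (both dialects + truth)."""
    validate_config(cfg)
    if "simulate" not in cfg["input"]:
        raise ValueError("config input has no 'simulate' section")
    seed = int(seed_override if seed_override is not None else cfg.get("seed", 0))
    reports, truth = generate(_synth_config(cfg, seed))
    write_database(reports, truth, out_dir)
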