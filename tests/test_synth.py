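import numpy as np
import pytest

from pvsignal import build_tables, deduplicate, filter_cohort, read_reports, ror, write_reports
from pvsignal.io import standardize_drug_names
from pvsignal.resources import load_default_dictionary, load_default_synonyms
from pvsignal.synth import SynthConfig, default_catalog, end_to_end_recovery, generate


def test_same_seed_reproduces_the_database_exactly():
    cfg = SynthConfig(n_cohort=100, n_background=400, planted=[("Abscess", 5.0)], seed=42)
    r1, t1 = generate(cfg)
    r2, t2 = generate(cfg)
    assert r1 == r2 and t1 == t2
    r3, _ = generate(SynthConfig(n_cohort=100, n_background=400,
                                 planted=[("Abscess", 5.0)], seed=43))
    assert r1 != r3


def test_duplicate_injection_and_removal():
    cfg = SynthConfig(n_cohort=200, n_background=800, duplicate_rate=0.2, seed=11)
    reports, _ = generate(cfg)
    assert len(reports) == 1200  # 1000 cases + 200 version-2 resubmissions
    assert len(deduplicate(reports)) == 1000


def test_config_validation_names_offending_field():
    with pytest.raises(ValueError, match="n_cohort"):
        SynthConfig(n_cohort=0).validate()
    with pytest.raises(ValueError, match="duplicate_rate"):
        SynthConfig(duplicate_rate=1.5).validate()
    with pytest.raises(ValueError, match="rate_ratio"):
        SynthConfig(planted=[("Abscess", -1.0)]).validate()
    with pytest.raises(ValueError, match="not in pt_catalog"):
        SynthConfig(planted=[("Qqqq", 2.0)]).validate()
    with pytest.raises(ValueError, match="missing_rates"):
        SynthConfig(missing_rates={"sex": 2.0}).validate()


def test_every_report_has_reactions_and_cohort_carries_target_drug():
    cfg = SynthConfig(n_cohort=150, n_background=300, seed=7)
    reports, _ = generate(cfg)
    assert all(r.reactions for r in reports)
    cohort = reports[:150]
    assert all(
        r.drugs[0].name in ("USTEKINUMAB", "STELARA")
        and r.drugs[0].indication_pt == "Crohn's disease"
        for r in cohort
    )


def test_background_marginal_pt_rates_match_catalog():
    """Law-of-large-numbers check on the PT marginals.

    Conditioning on a non-empty reaction set (empty rows are redrawn)
    scales every marginal to exactly r/(1-p0) with p0 = prod(1-r_j), so
    the empirical rates must converge to that conditional value.
    """
    n = 30000
    reports, _ = generate(SynthConfig(n_cohort=1, n_background=n, seed=5))
    bg = reports[1 : n + 1]
    counts = {}
    for r in bg:
        for pt in r.pt_set():
            counts[pt] = counts.get(pt, 0) + 1
    p0 = np.prod([1 - s.rate for s in default_catalog()])
    for spec in default_catalog():
        if spec.rate < 0.003:
            continue
        expected = spec.rate / (1 - p0)
        se = np.sqrt(expected * (1 - expected) / n)
        assert counts.get(spec.pt, 0) / n == pytest.approx(expected, abs=3 * se)


def test_generated_database_round_trips_through_both_dialects(tmp_path):
    cfg = SynthConfig(n_cohort=40, n_background=160, duplicate_rate=0.1, seed=9)
    reports, _ = generate(cfg)
    write_reports(reports, tmp_path / "norm", dialect="normalized-csv")
    assert read_reports(tmp_path / "norm", dialect="normalized-csv") == reports
    write_reports(reports, tmp_path / "faers", dialect="faers-ascii")
    back = read_reports(tmp_path / "faers", dialect="faers-ascii")
    assert len(back) == len(reports)
    assert sorted(r.pt_set() for r in back) == sorted(r.pt_set() for r in reports)


def test_planted_pair_shows_elevated_ror():
    """RR=10 on a 1% background PT yields an empirical cohort ROR near 10."""
    cfg = SynthConfig(n_cohort=5000, n_background=20000, duplicate_rate=0.0,
                      planted=[("Abscess", 10.0)], seed=17)
    reports, truth = generate(cfg)
    reports = standardize_drug_names(reports, load_default_synonyms())
    cohort, background = filter_cohort(
        deduplicate(reports), "ustekinumab", {"Crohn's disease"}, ("2016Q4", "2023Q4")
    )
    t = build_tables(cohort, background)["Abscess"]
    assert 6 <= ror(t)[0] <= 16


def test_end_to_end_with_no_planting_reports_na_sensitivity():
    rep = end_to_end_recovery(SynthConfig(n_cohort=300, n_background=3000, seed=23))
    assert rep["sensitivity"] is None
    assert 0 <= rep["fp_rate"] <= 1


def test_default_catalog_is_covered_by_packaged_dictionary():
    d = load_default_dictionary()
    for spec in default_catalog():
        assert d.soc_of(spec.pt) == spec.soc
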