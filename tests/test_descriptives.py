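import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal import (
    compute_tto,
    death_proportion_by_soc,
    summarize_demographics,
    summarize_tto,
    yearly_counts,
)
from pvsignal.descriptives import TTORecord, round2

from conftest import make_report


def block(table, name):
    sub = table[table["block"] == name]
    return dict(zip(sub["category"], zip(sub["count"], sub["pct"])))


# ------------------------------------------------------------ demographics


def test_sex_percentages():
    cohort = [make_report(f"F{i}") for i in range(2)] + [
        make_report(f"M{i}", sex="male") for i in range(5)
    ]
    out = summarize_demographics(cohort)
    sex = block(out["table"], "sex")
    assert sex["female"] == (2, round2(200 / 7))
    assert sex["male"] == (5, round2(500 / 7))


def test_all_missing_sex_is_one_category():
    cohort = [make_report(f"R{i}", sex="unspecified") for i in range(4)]
    sex = block(summarize_demographics(cohort)["table"], "sex")
    assert sex["unspecified"] == (4, 100.0)


def test_age_median_and_iqr_use_linear_interpolation():
    cohort = [make_report(f"R{i}", age=a) for i, a in enumerate((31.0, 45.0, 59.0))]
    out = summarize_demographics(cohort)
    assert out["age_median"] == 45.0
    assert (out["age_q1"], out["age_q3"]) == (38.0, 52.0)


def test_age_bands():
    ages = [5.0, 25.0, 35.0, 45.0, 55.0, 75.0, None]
    cohort = [make_report(f"R{i}", age=a) for i, a in enumerate(ages)]
    bands = block(summarize_demographics(cohort)["table"], "age_band")
    for cat in ("<20", "20–29", "30–39", "40–49", "50–59", "≥60", "unspecified"):
        assert bands[cat][0] == 1


def test_exhaustive_percentage_blocks_sum_to_100():
    from pvsignal.synth import SynthConfig, generate

    cohort, _ = generate(SynthConfig(n_cohort=400, n_background=1, seed=2))
    out = summarize_demographics(cohort[:400])
    for name in ("sex", "age_band", "reporter"):
        total = sum(p for _, p in block(out["table"], name).values())
        assert total == pytest.approx(100.0, abs=0.05)


# ------------------------------------------------------------------- TTO


def test_tto_worked_example():
    r = make_report("A", therapy_start=dt.date(2020, 1, 1), event_date=dt.date(2020, 3, 21))
    rec = compute_tto(r, "ustekinumab")
    assert rec.tto_days == 80
    assert rec.bin == "≥60"


def test_tto_negative_or_missing_is_unspecified():
    r = make_report("A", therapy_start=dt.date(2020, 3, 21), event_date=dt.date(2020, 1, 1))
    assert compute_tto(r, "ustekinumab").bin == "unspecified"
    assert compute_tto(make_report("B"), "ustekinumab").bin == "unspecified"
    # therapy start on another drug does not count
    r2 = make_report("C", drug="infliximab", therapy_start=dt.date(2020, 1, 1),
                     event_date=dt.date(2020, 2, 1))
    assert compute_tto(r2, "ustekinumab").bin == "unspecified"


@pytest.mark.parametrize("days,expected", [(0, "<7"), (6, "<7"), (7, "7–28"),
                                           (27, "7–28"), (28, "28–60"),
                                           (59, "28–60"), (60, "≥60"), (400, "≥60")])
def test_tto_bin_boundaries_are_half_open(days, expected):
    start = dt.date(2020, 1, 1)
    r = make_report("A", therapy_start=start, event_date=start + dt.timedelta(days=days))
    rec = compute_tto(r, "ustekinumab")
    assert (rec.tto_days, rec.bin) == (days, expected)


@settings(derandomize=True, max_examples=80)
@given(days=st.integers(min_value=-400, max_value=2000))
def test_tto_bin_consistent_with_days(days):
    start = dt.date(2018, 6, 15)
    r = make_report("A", therapy_start=start, event_date=start + dt.timedelta(days=days))
    rec = compute_tto(r, "ustekinumab")
    if days < 0:
        assert rec.tto_days is None and rec.bin == "unspecified"
    else:
        assert rec.tto_days == days
        TTORecord(rec.case_id, rec.tto_days, rec.bin)  # validates consistency


def test_tto_record_rejects_inconsistent_bin():
    with pytest.raises(ValueError):
        TTORecord("A", 5, "7–28")


def test_summarize_tto_counts_and_median():
    start = dt.date(2020, 1, 1)
    cohort = [
        make_report(f"R{d}", therapy_start=start, event_date=start + dt.timedelta(days=d))
        for d in (1, 10, 40, 80, 120)
    ] + [make_report("missing")]
    out = summarize_tto(cohort, "ustekinumab")
    counts = dict(zip(out["table"]["category"], out["table"]["count"]))
    assert counts == {"<7": 1, "7–28": 1, "28–60": 1, "≥60": 2, "unspecified": 1}
    assert out["tto_median"] == 40.0
    assert out["n_classifiable"] == 5


# ------------------------------------------------------------- fatalities


def test_death_proportion_by_soc(toy_dictionary):
    cohort = (
        [make_report(f"D{i}", pts=("Myocardial infarction",), outcomes={"DE"})
         for i in range(24)]
        + [make_report(f"S{i}", pts=("Myocardial infarction",)) for i in range(296)]
        + [make_report(f"H{i}", pts=("Cholangitis",),
                       outcomes={"DE"} if i < 8 else {"HO"}) for i in range(357)]
        + [make_report(f"N{i}", pts=("Nausea",)) for i in range(100)]
    )
    df = death_proportion_by_soc(cohort, toy_dictionary)
    rows = {r.soc: r for r in df.itertuples()}
    assert rows["Cardiac disorders"].deaths == 24
    assert rows["Cardiac disorders"].total == 320
    assert rows["Cardiac disorders"].death_pct == 7.50
    assert rows["Hepatobiliary disorders"].death_pct == 2.24
    assert rows["Gastrointestinal disorders"].death_pct == 0.00
    assert all(r.deaths <= r.total for r in df.itertuples())
    assert all(0 <= r.death_pct <= 100 for r in df.itertuples())


def test_death_report_counts_once_per_soc(toy_dictionary):
    cohort = [make_report("A", pts=("Abscess", "Pneumonia", "Nausea"), outcomes={"DE"})]
    df = death_proportion_by_soc(cohort, toy_dictionary)
    rows = {r.soc: r for r in df.itertuples()}
    assert rows["Infections and infestations"].total == 1
    assert rows["Gastrointestinal disorders"].deaths == 1


# ----------------------------------------------------------------- yearly


def test_yearly_counts_partition():
    cohort = [make_report(f"R{i}", receipt=f"20{18 + i % 3}-06-01") for i in range(9)]
    df = yearly_counts(cohort)
    assert df["count"].sum() == 9
    assert df["pct"].sum() == pytest.approx(100.0, abs=0.05)


def test_single_year_is_100_percent():
    df = yearly_counts([make_report("A"), make_report("B")])
    assert list(df["pct"]) == [100.0]
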