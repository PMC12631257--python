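import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import psi

from pvsignal import ContingencyTable, MgpsPrior, ebgm, fit_mgps_prior, ic_bcpnn, mc_ic_oracle, prr, ror
from pvsignal.dispro import ebgm05_mc, mixture_loglik

WORKED = ContingencyTable(10, 90, 100, 9900)
INDEP = ContingencyTable(5, 45, 95, 855)


# ---------------------------------------------------------------- ROR/PRR


def test_ror_worked_example():
    point, lo, hi = ror(WORKED)
    assert point == pytest.approx(11.0)
    # Woolf CI recomputed independently from the log-scale SE
    se = math.sqrt(1 / 10 + 1 / 90 + 1 / 100 + 1 / 9900)
    assert lo == pytest.approx(math.exp(math.log(11.0) - 1.96 * se))
    assert (round(lo, 2), round(hi, 2)) == (5.56, 21.76)


def test_prr_worked_example():
    point, lo, hi = prr(WORKED)
    assert point == pytest.approx(10.0)
    assert lo < point < hi


def test_independence_gives_exactly_one():
    assert ror(INDEP)[0] == pytest.approx(1.0, abs=1e-12)
    assert prr(INDEP)[0] == pytest.approx(1.0, abs=1e-12)


def test_zero_cells_are_non_computable():
    assert all(math.isnan(v) for v in ror(ContingencyTable(5, 0, 10, 100)))
    assert all(math.isnan(v) for v in ror(ContingencyTable(5, 10, 0, 100)))
    assert all(math.isnan(v) for v in prr(ContingencyTable(5, 10, 0, 100)))


def test_ci_brackets_point_on_all_positive_tables():
    for t in [WORKED, INDEP, ContingencyTable(3, 7, 11, 200)]:
        r, rlo, rhi = ror(t)
        p, plo, phi = prr(t)
        assert rlo <= r <= rhi
        assert plo <= p <= phi


def test_scaling_counts_preserves_point_and_narrows_ci():
    t1 = ContingencyTable(10, 90, 100, 9900)
    t2 = ContingencyTable(100, 900, 1000, 99000)
    r1, lo1, hi1 = ror(t1)
    r2, lo2, hi2 = ror(t2)
    assert r2 == pytest.approx(r1)
    assert (hi2 - lo2) < (hi1 - lo1)
    p1 = prr(t1)
    p2 = prr(t2)
    assert p2[0] == pytest.approx(p1[0])
    assert (p2[2] - p2[1]) < (p1[2] - p1[1])


@settings(derandomize=True, max_examples=50)
@given(
    a=st.integers(min_value=0, max_value=40),
    b=st.integers(min_value=50, max_value=500),
    c=st.integers(min_value=50, max_value=500),
    d=st.integers(min_value=5000, max_value=50000),
)
def test_statistics_are_monotone_in_a(a, b, c, d):
    """Adding target-drug cases never lowers any estimate (background-dominated
    tables; for IC/EBGM the expected count E grows with a as well, so the
    property needs the background to dwarf the cohort, as it does in practice)."""
    prior = MgpsPrior(0.5, 0.5, 2.0, 2.0, 0.4)
    t0, t1 = ContingencyTable(a, b, c, d), ContingencyTable(a + 1, b, c, d)
    if a > 0:
        assert ror(t1)[0] >= ror(t0)[0]
        assert prr(t1)[0] >= prr(t0)[0]
    assert ic_bcpnn(t1)[0] >= ic_bcpnn(t0)[0]
    assert ebgm(t1, prior)[0] >= ebgm(t0, prior)[0] - 1e-9


# -------------------------------------------------------------------- IC


def test_ic_worked_example():
    ic, ic025 = ic_bcpnn(WORKED)
    E = 100 * 110 / 10100
    assert ic == pytest.approx(math.log2(10.5 / (E + 0.5)), abs=1e-12)
    assert ic == pytest.approx(2.724, abs=1e-3)
    assert ic025 == pytest.approx(2.724 - 3.3 / math.sqrt(10.5) - 2 / 10.5**1.5, abs=1e-3)
    assert ic025 == pytest.approx(1.647, abs=1e-3)


def test_ic_zero_when_observed_matches_expected():
    t = ContingencyTable(1, 9, 9, 81)  # E = 10*10/100 = 1, a = 1
    ic, _ = ic_bcpnn(t)
    assert ic == 0.0


def test_ic_negative_when_event_deficit():
    t = ContingencyTable(0, 100, 500, 400)  # E = 50
    assert ic_bcpnn(t)[0] < 0


def test_mc_oracle_is_seed_deterministic():
    assert mc_ic_oracle(WORKED, seed=7) == mc_ic_oracle(WORKED, seed=7)
    assert mc_ic_oracle(WORKED, seed=7) != mc_ic_oracle(WORKED, seed=8)
    with pytest.raises(ValueError):
        mc_ic_oracle(WORKED, draws=10)


def test_mc_oracle_agrees_and_converges():
    ic, _ = ic_bcpnn(WORKED)
    mc, _ = mc_ic_oracle(WORKED, draws=200_000, seed=1)
    assert abs(ic - mc) < 0.15
    big = ContingencyTable(1000, 9000, 10000, 990000)
    ic_b, _ = ic_bcpnn(big)
    mc_b, _ = mc_ic_oracle(big, draws=200_000, seed=1)
    assert abs(ic_b - mc_b) < abs(ic - mc)


def test_mc_oracle_on_table_grid():
    """Closed form vs sampled posterior across a spread of table shapes."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = int(rng.integers(3, 200))
        b = int(rng.integers(10, 2000))
        c = int(rng.integers(10, 2000))
        d = int(rng.integers(1000, 50000))
        t = ContingencyTable(a, b, c, d)
        ic, _ = ic_bcpnn(t)
        mc, _ = mc_ic_oracle(t, draws=100_000, seed=2)
        assert abs(ic - mc) < max(0.15, 1.5 / a)


# ------------------------------------------------------------------ EBGM


def test_ebgm_degenerate_prior_matches_digamma_closed_form():
    t = ContingencyTable(10, 90, 0, 900)  # E = 1 exactly
    prior = MgpsPrior(2.0, 4.0, 2.0, 4.0, 0.5)  # both components Gamma(2,4)
    point, _ = ebgm(t, prior)
    assert point == pytest.approx(math.exp(psi(12)) / 5, abs=1e-9)
    assert point == pytest.approx(2.301, abs=1e-3)


def test_ebgm_shrinks_extreme_ratios_toward_prior():
    t = ContingencyTable(100, 0, 0, 999900)  # a/E huge
    assert t.a / t.E > 500
    prior = MgpsPrior(1.0, 1.0, 2.0, 2.0, 0.5)
    point, _ = ebgm(t, prior)
    assert point < t.a / t.E


def test_eb05_below_point_estimate_on_table_grid():
    prior = MgpsPrior(0.2, 0.1, 2.0, 4.0, 1 / 3)
    rng = np.random.default_rng(1)
    for _ in range(15):
        t = ContingencyTable(
            int(rng.integers(0, 100)), int(rng.integers(1, 1000)),
            int(rng.integers(1, 1000)), int(rng.integers(100, 100000)),
        )
        point, lo = ebgm(t, prior)
        assert lo < point


def test_eb05_root_finder_matches_mc_quantile():
    prior = MgpsPrior(0.2, 0.1, 2.0, 4.0, 1 / 3)
    t = ContingencyTable(50, 4950, 100, 99900)
    _, lo = ebgm(t, prior)
    mc = ebgm05_mc(t, prior, draws=10**6, seed=3)
    assert lo == pytest.approx(mc, rel=0.02)


def test_ebgm_percentile_option():
    prior = MgpsPrior(0.2, 0.1, 2.0, 4.0, 1 / 3)
    t = ContingencyTable(50, 4950, 100, 99900)
    _, eb05 = ebgm(t, prior, percentile=0.05)
    _, eb025 = ebgm(t, prior, percentile=0.025)
    assert eb025 < eb05
    with pytest.raises(ValueError):
        ebgm(t, prior, percentile=0.6)


# ------------------------------------------------------------- MGPS fit


def test_prior_fit_is_optimal_and_scale_invariant():
    rng = np.random.default_rng(9)
    true = (0.2, 0.1, 2.0, 4.0, 1 / 3)
    n = 2000
    E = np.exp(rng.uniform(np.log(0.1), np.log(100), size=n))
    comp = rng.random(n) < true[4]
    lam = np.where(comp, rng.gamma(true[0], 1 / true[1], n), rng.gamma(true[2], 1 / true[3], n))
    a = rng.poisson(lam * E)
    prior = fit_mgps_prior(a, E, seed=0)
    fitted = (prior.alpha1, prior.beta1, prior.alpha2, prior.beta2, prior.w)
    assert mixture_loglik(fitted, a, E) >= mixture_loglik(true, a, E) - 1e-6
    # duplicating every cell scales the likelihood but not its argmax
    prior2 = fit_mgps_prior(np.tile(a, 2), np.tile(E, 2), seed=0)
    assert (prior2.alpha1, prior2.beta1, prior2.w) == pytest.approx(
        (prior.alpha1, prior.beta1, prior.w), rel=1e-4
    )


def test_prior_fit_rejects_bad_input():
    with pytest.raises(ValueError):
        fit_mgps_prior([1, 2, 3], [1.0, 2.0], seed=0)
    with pytest.raises(ValueError):
        fit_mgps_prior([1] * 10, [0.0] * 10, seed=0)
    with pytest.raises(ValueError):
        MgpsPrior(1.0, 1.0, 1.0, 1.0, 1.5)
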