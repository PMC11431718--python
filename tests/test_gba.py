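import numpy as np
import pytest
from scipy.stats import chi2

from taucor import (WeightScheme, acat_combine, acat_test, burden_test,
                    pca_test, quadform_pvalue, skat_test, skato_test)
from taucor.gba import quadform_logsf
from conftest import random_correlation, random_partition_blocks


# ------------------------------------------------------------- quadform

def test_quadform_single_lambda_is_chi2():
    assert quadform_pvalue(3.841, np.array([1.0])) == pytest.approx(0.0500, abs=5e-4)


def test_quadform_equal_lambdas_is_chi2_df3():
    assert quadform_pvalue(3.0, np.ones(3)) == pytest.approx(
        chi2.sf(3.0, 3), rel=1e-10)
    assert quadform_pvalue(3.0, np.ones(3)) == pytest.approx(0.3916, abs=5e-4)


def test_quadform_matches_monte_carlo():
    lam = np.array([2.0, 0.5])
    rng = np.random.default_rng(42)
    draws = (lam * rng.chisquare(1, size=(200_000, 2))).sum(axis=1)
    p_mc = float(np.mean(draws > 4.0))
    se = np.sqrt(p_mc * (1 - p_mc) / draws.size)
    assert quadform_pvalue(4.0, lam) == pytest.approx(p_mc, abs=3 * se)


def test_quadform_zero_lambdas_dropped_and_all_zero_rejected():
    p_with_zeros = quadform_pvalue(3.0, np.array([1.0, 0.0, 1.0, 1.0, 0.0]))
    assert p_with_zeros == pytest.approx(chi2.sf(3.0, 3), rel=1e-10)
    with pytest.raises(ValueError):
        quadform_pvalue(1.0, np.zeros(3))


def test_quadform_deep_tail_log_scale():
    lam = np.array([2.0, 0.5, 0.3])
    lp1, meta1 = quadform_logsf(100.0, lam)
    lp2, meta2 = quadform_logsf(500.0, lam)
    assert meta2["method"] == "saddlepoint"
    assert lp2 < lp1 < 0
    assert np.isfinite(lp2) and lp2 / np.log(10) < -30  # far below 1e-30


def test_quadform_tail_methods_agree_where_both_work():
    from taucor.gba import _imhof_sf, _saddlepoint_logsf
    lam = np.array([1.7, 0.9, 0.4, 0.1])
    for q in [5.0, 12.0, 25.0]:
        p_imhof, _ = _imhof_sf(q, lam)
        p_sp = np.exp(_saddlepoint_logsf(q, lam))
        assert p_sp == pytest.approx(p_imhof, rel=0.15)


# ------------------------------------------------------------- burden

def test_burden_identity_example():
    r = burden_test(np.ones(3), np.eye(3))
    assert r.statistic == pytest.approx(3.0)
    assert r.p == pytest.approx(chi2.sf(3.0, 1), rel=1e-10)
    assert r.p == pytest.approx(0.0833, abs=5e-4)


def test_burden_null_point():
    r = burden_test(np.zeros(4), np.eye(4))
    assert r.statistic == 0.0 and r.p == 1.0


def test_burden_p_grows_with_rank_one_inflation(rng):
    z = rng.normal(size=5)
    Sigma = random_correlation(rng, 5)
    c = rng.normal(size=5)
    p1 = burden_test(z, Sigma).p
    p2 = burden_test(z, Sigma + np.outer(c, c)).p
    assert p2 >= p1


def test_burden_degenerate_variance_rejected():
    with pytest.raises(ValueError):
        burden_test(np.ones(2), np.zeros((2, 2)))


# ------------------------------------------------------------- skat

def test_skat_identity_example():
    r = skat_test(np.ones(3), np.eye(3))
    assert r.statistic == pytest.approx(3.0)
    assert r.p == pytest.approx(0.3916, abs=5e-4)


def test_skat_single_snp_equals_burden(rng):
    z = np.array([1.7])
    Sigma = np.array([[1.4]])
    assert skat_test(z, Sigma).p == pytest.approx(burden_test(z, Sigma).p, rel=1e-10)


def test_skat_null_point():
    assert skat_test(np.zeros(3), np.eye(3)).p == 1.0


def test_skat_weights_scale_mixture(rng):
    # doubling all weights multiplies Q and every lambda by 4: p unchanged
    z = rng.normal(size=4)
    Sigma = random_correlation(rng, 4)
    p1 = skat_test(z, Sigma, WeightScheme(np.full(4, 1.0))).p
    p2 = skat_test(z, Sigma, WeightScheme(np.full(4, 2.0))).p
    assert p2 == pytest.approx(p1, rel=1e-9)


# ------------------------------------------------------------- skat-o

def test_skato_rho_one_is_burden(rng):
    z = rng.normal(size=4)
    Sigma = random_correlation(rng, 4)
    r = skato_test(z, Sigma, rho_grid=(1.0,))
    b = burden_test(z, Sigma)
    assert (r.p, r.log10p, r.statistic) == (b.p, b.log10p, b.statistic)


def test_skato_rho_zero_is_skat(rng):
    z = rng.normal(size=4)
    Sigma = random_correlation(rng, 4)
    r = skato_test(z, Sigma, rho_grid=(0.0,))
    s = skat_test(z, Sigma)
    assert (r.p, r.log10p) == (s.p, s.log10p)


def test_skato_grid_must_bracket(rng):
    with pytest.raises(ValueError, match="0 and 1"):
        skato_test(np.ones(3), np.eye(3), rho_grid=(0.2, 0.5))


def test_skato_combination_bounds(rng):
    for _ in range(25):
        m = int(rng.integers(2, 7))
        z = rng.normal(0, 1.5, size=m)
        Sigma = random_correlation(rng, m)
        r = skato_test(z, Sigma)
        per_rho_p = [10.0**lp for lp in r.meta["per_rho_log10p"]]
        assert r.p <= 1.0
        assert r.p >= min(per_rho_p) * (1 - 1e-9)
        assert r.meta["rho_min"] in (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


# ------------------------------------------------------------- pca

def test_pca_identity_full_fraction(rng):
    z = rng.normal(size=6)
    r = pca_test(z, np.eye(6), var_fraction=1.0)
    assert r.meta["df"] == 6
    assert r.statistic == pytest.approx(float(z @ z))


def test_pca_rank_one_component():
    z = np.array([0.5, 1.0, -0.2])
    r = pca_test(z, np.ones((3, 3)), var_fraction=0.85)
    assert r.meta["df"] == 1
    # single component (1,1,1)/sqrt(3) with eigenvalue 3: T = (sum z)^2 / 9
    assert r.statistic == pytest.approx(np.sum(z) ** 2 / 9.0, rel=1e-10)


def test_pca_null_point():
    assert pca_test(np.zeros(3), np.eye(3)).p == 1.0


def test_pca_rejects_zero_spectrum():
    with pytest.raises(ValueError):
        pca_test(np.ones(2), np.zeros((2, 2)))


# ------------------------------------------------------------- ACAT

def test_acat_median_point():
    assert acat_combine([0.5]) == pytest.approx(0.5, abs=1e-12)


@pytest.mark.parametrize("p_star", [0.7, 0.3, 0.01, 1e-6])
def test_acat_identical_components_identity(p_star):
    assert acat_combine([p_star] * 4) == pytest.approx(p_star, rel=1e-9)


def test_acat_two_value_example():
    expect = 0.5 - np.arctan(np.tan(0.49 * np.pi) / 2.0) / np.pi
    got = acat_combine([0.01, 0.5])
    assert got == pytest.approx(expect, rel=1e-10)
    assert got == pytest.approx(0.0198, abs=3e-4)


def test_acat_tiny_p_no_overflow():
    p = acat_combine([1e-200, 0.5])
    assert 0 < p < 1e-190  # dominated by the tiny component halved


def test_acat_empty_rejected():
    with pytest.raises(ValueError):
        acat_combine([])


def test_acat_test_uses_log10p_below_double_underflow():
    from taucor.gba import GBAResult
    r1 = GBAResult("skat", 1.0, 1e-300, -320.0, {})
    r2 = GBAResult("pca", 1.0, 0.5, np.log10(0.5), {})
    comb = acat_test([r1, r2])
    assert comb.log10p == pytest.approx(-320.0 + np.log10(2.0), abs=1e-6)


# ----------------------------------------------- conditional monotonicity

def test_kernel_tests_monotone_under_background_adjustment(rng):
    """Inflating the null covariance by tau * U_gr U_gr' can only raise the
    Burden/SKAT/SKAT-O p-value, for any data and any tau >= 0."""
    for _ in range(300):
        mg = int(rng.integers(1, 8))
        mr = int(rng.integers(1, 11))
        U_g, _, U_gr = random_partition_blocks(rng, mg, mr)
        tau = float(rng.uniform(0, 6))
        z = rng.normal(0, 2.0, size=mg)
        sigma = tau * U_gr @ U_gr.T + U_g
        for fn in (burden_test, skat_test, skato_test):
            lp_init = fn(z, U_g).log10p
            lp_cond = fn(z, sigma).log10p
            assert lp_cond >= lp_init - 1e-9, fn.__name__


def test_pca_loses_monotonicity():
    """The PCA test does not inherit the guarantee: a seeded random search
    finds an instance where adjustment makes the p-value smaller."""
    rng = np.random.default_rng(0)
    for _ in range(500):
        mg = int(rng.integers(2, 8))
        mr = int(rng.integers(2, 10))
        U_g, _, U_gr = random_partition_blocks(rng, mg, mr)
        tau = float(rng.uniform(0.1, 5))
        z = rng.normal(0, 2, mg)
        sigma = tau * U_gr @ U_gr.T + U_g
        if pca_test(z, sigma).p < pca_test(z, U_g).p - 1e-12:
            return
    pytest.fail("no PCA counterexample found in 500 seeded draws")


def test_results_deterministic(rng):
    z = rng.normal(size=5)
    Sigma = random_correlation(rng, 5)
    for fn in (burden_test, skat_test, skato_test, pca_test):
        r1, r2 = fn(z, Sigma), fn(z, Sigma)
        assert r1.p == r2.p and r1.log10p == r2.log10p


# ------------------------------------------------- hypothesis properties

from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=50, deadline=None)
@given(p_star=st.floats(1e-10, 1 - 1e-10), k=st.integers(1, 6))
def test_acat_identity_property(p_star, k):
    """Combining k copies of the same p-value returns it unchanged."""
    assert acat_combine([p_star] * k) == pytest.approx(p_star, rel=1e-6)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(seed=st.integers(0, 2**31 - 1), tau=st.floats(0.0, 10.0))
def test_burden_monotone_in_tau_property(seed, tau):
    """Burden p is nondecreasing in the background variance tau."""
    rng = np.random.default_rng(seed)
    mg, mr = 4, 6
    U_g, _, U_gr = random_partition_blocks(rng, mg, mr)
    z = rng.normal(0, 2, mg)
    p0 = burden_test(z, U_g).log10p
    p1 = burden_test(z, tau * U_gr @ U_gr.T + U_g).log10p
    assert p1 >= p0 - 1e-9
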