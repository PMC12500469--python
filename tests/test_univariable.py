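"""Univariable estimators, diagnostics and their independent oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import mrselect as mr
from mrselect.univariable import (
    _weighted_median_point,
    _weighted_mode_point,
    modified_silverman_bandwidth,
)

from conftest import make_hset, make_table


# ------------------------------------------------------------- Wald ratio

def test_wald_ratio_basic_identities():
    assert mr.wald_ratio(1.0, 0.1, 0.0, 0.1).theta_j == 0.0
    est = mr.wald_ratio(2.0, 0.1, 1.0, 0.2)
    assert est.theta_j == pytest.approx(0.5)
    assert est.se_j == pytest.approx(0.1)
    assert est.weight_j == pytest.approx(1.0 / 0.1**2)
    with pytest.raises(mr.DegenerateInstrumentError):
        mr.wald_ratio(0.0, 0.1, 0.5, 0.1)


def test_wald_ratio_se_matches_monte_carlo():
    # first-order SE against the sampling SD of Gamma*/gamma, 1e5 draws
    rng = np.random.default_rng(5)
    gamma, Gamma, Gamma_se = 0.25, 0.1, 0.02
    draws = rng.normal(Gamma, Gamma_se, 100_000) / gamma
    est = mr.wald_ratio(gamma, 0.01, Gamma, Gamma_se)
    assert est.se_j == pytest.approx(np.std(draws), rel=0.02)


# --------------------------------------------------------------------- IVW

def test_ivw_consensus_and_degenerate_cases():
    hs = make_hset([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.1, 0.2], [0.02] * 3)
    assert mr.ivw(hs).beta == pytest.approx(0.5)  # all ratios exactly 0.5
    dup = make_hset([0.2, 0.2], [0.01] * 2, [0.1, 0.1], [0.02] * 2)
    assert mr.ivw(dup).beta == pytest.approx(mr.wald_ratio(0.2, 0.01, 0.1, 0.02).theta_j)
    with pytest.raises(mr.InsufficientInstrumentsError):
        mr.ivw(make_hset([0.2], [0.01], [0.1], [0.02]))


def test_ivw_matches_hand_computed_weighted_mean():
    g = np.array([0.1, 0.15, 0.2, 0.25, 0.3])
    Gse = np.array([0.02, 0.03, 0.02, 0.04, 0.03])
    G = np.array([0.03, 0.02, 0.09, 0.11, 0.10])
    hs = make_hset(g, [0.01] * 5, G, Gse)
    theta = G / g
    w = g**2 / Gse**2
    assert mr.ivw(hs).beta == pytest.approx(np.sum(w * theta) / np.sum(w), abs=1e-12)
    assert mr.ivw(hs).se == pytest.approx(np.sum(w) ** -0.5, abs=1e-12)


def test_ivw_random_effects_never_shrinks_se():
    g = np.array([0.1, 0.15, 0.2, 0.25, 0.3])
    hs = make_hset(g, [0.01] * 5, [0.09, 0.01, 0.12, 0.02, 0.15], [0.02] * 5)
    assert mr.ivw(hs, "multiplicative_random").se >= mr.ivw(hs, "fixed").se


@given(st.permutations(range(6)), st.lists(st.sampled_from([1.0, -1.0]), min_size=6, max_size=6))
def test_ivw_invariant_to_order_and_joint_sign_flips(perm, signs):
    rng = np.random.default_rng(0)
    g = rng.uniform(0.1, 0.3, 6)
    G = 0.3 * g + rng.normal(0, 0.01, 6)
    Gse = rng.uniform(0.01, 0.03, 6)
    base = mr.ivw(make_hset(g, [0.01] * 6, G, Gse)).beta
    s = np.asarray(signs)
    p = np.asarray(perm)
    flipped = mr.ivw(make_hset((g * s)[p], [0.01] * 6, (G * s)[p], Gse[p])).beta
    assert flipped == pytest.approx(base, abs=1e-12)


# ------------------------------------------------------------------ Egger

def test_egger_exact_line_through_origin_equals_ivw():
    g = np.array([0.1, 0.15, 0.2, 0.25, 0.3, 0.12])
    hs = make_hset(g, [0.01] * 6, 0.3 * g, [0.02] * 6)
    slope, intercept = mr.mr_egger(hs)
    assert slope.beta == pytest.approx(0.3, abs=1e-10)
    assert intercept.beta == pytest.approx(0.0, abs=1e-10)
    assert mr.ivw(hs).beta == pytest.approx(slope.beta, abs=1e-10)


def test_egger_exact_affine_data():
    g = np.array([0.1, 0.15, 0.2, 0.25, 0.3, 0.12])
    hs = make_hset(g, [0.01] * 6, 0.1 + 0.3 * g, [0.02] * 6)
    slope, intercept = mr.mr_egger(hs)
    assert slope.beta == pytest.approx(0.3, abs=1e-10)
    assert intercept.beta == pytest.approx(0.1, abs=1e-10)


def test_egger_matches_normal_equations_oracle():
    rng = np.random.default_rng(3)
    g = rng.uniform(0.05, 0.3, 6)
    Gse = rng.uniform(0.01, 0.04, 6)
    G = 0.05 + 0.25 * g + rng.normal(0, 0.02, 6)
    hs = make_hset(g, [0.01] * 6, G, Gse)
    slope, intercept = mr.mr_egger(hs)
    # independent WLS solve of the 2x2 normal equations
    w = 1 / Gse**2
    sw, swx, swxx = w.sum(), (w * g).sum(), (w * g * g).sum()
    swy, swxy = (w * G).sum(), (w * g * G).sum()
    det = sw * swxx - swx**2
    a = (swxx * swy - swx * swxy) / det
    b = (sw * swxy - swx * swy) / det
    assert intercept.beta == pytest.approx(a, abs=1e-12)
    assert slope.beta == pytest.approx(b, abs=1e-12)


def test_egger_orients_negative_gamma_rows():
    g = np.array([0.1, -0.15, 0.2, -0.25, 0.3])
    G = 0.3 * g
    hs = make_hset(g, [0.01] * 5, G, [0.02] * 5)
    slope, _ = mr.mr_egger(hs)
    assert slope.beta == pytest.approx(0.3, abs=1e-10)


# ---------------------------------------------------------- weighted median

def test_weighted_median_simple_cases():
    hs = make_hset([1, 1, 1], [0.01] * 3, [1, 2, 9], [1, 1, 1])
    assert mr.weighted_median(hs, n_boot=2, seed=0).beta == pytest.approx(2.0)
    hs2 = make_hset([0.1, 0.2, 0.3], [0.01] * 3, [0.07, 0.14, 0.21], [0.01, 0.03, 0.02])
    assert mr.weighted_median(hs2, n_boot=2, seed=0).beta == pytest.approx(0.7)


def _median_oracle(theta, w):
    # brute-force interpolation of the weighted CDF at 0.5
    order = np.argsort(theta)
    t, p = np.asarray(theta)[order], np.asarray(w)[order] / np.sum(w)
    s = np.cumsum(p) - 0.5 * p
    return float(np.interp(0.5, s, t))


def test_weighted_median_matches_bruteforce_interpolation():
    rng = np.random.default_rng(8)
    g = rng.uniform(0.1, 0.4, 4)
    G = rng.normal(0.2, 0.1, 4) * g
    Gse = rng.uniform(0.01, 0.05, 4)
    hs = make_hset(g, [0.01] * 4, G, Gse)
    theta, w = G / g, g**2 / Gse**2
    assert mr.weighted_median(hs, n_boot=2, seed=0).beta == pytest.approx(
        _median_oracle(theta, w), abs=1e-12
    )


@given(st.integers(3, 15))
def test_weighted_median_equal_weights_is_sample_median(L):
    if L % 2 == 0:
        L += 1
    rng = np.random.default_rng(L)
    theta = rng.normal(0, 1, L)
    assert _weighted_median_point(theta, np.ones(L)) == pytest.approx(np.median(theta))


# ------------------------------------------------------------ weighted mode

def test_weighted_mode_dominant_cluster():
    theta = np.array([1.5] * 7 + [0.1, 3.0, -2.0])
    g = np.full(10, 0.2)
    hs = make_hset(g, [0.01] * 10, theta * g, [0.02] * 10)
    est = mr.weighted_mode(hs, n_boot=2, seed=0)
    h = modified_silverman_bandwidth(theta)
    assert est.beta == pytest.approx(1.5, abs=max(0.02, h / 5))


def test_weighted_mode_consensus():
    g = np.array([0.1, 0.2, 0.3])
    hs = make_hset(g, [0.01] * 3, 0.7 * g, [0.02] * 3)
    assert mr.weighted_mode(hs, n_boot=2, seed=0).beta == pytest.approx(0.7)


def test_weighted_mode_bimodal_matches_fine_grid_oracle():
    rng = np.random.default_rng(9)
    theta = np.concatenate([rng.normal(0.2, 0.05, 12), rng.normal(1.0, 0.05, 6)])
    w = rng.uniform(0.5, 2.0, 18)
    coarse = _weighted_mode_point(theta, w, 1.0, 1024)
    fine = _weighted_mode_point(theta, w, 1.0, 10_240)
    span = theta.max() - theta.min() + 6 * modified_silverman_bandwidth(theta)
    assert abs(coarse - fine) <= span / 1024  # within one coarse grid step


# -------------------------------------------------- mean F and heterogeneity

def test_mean_instrument_f_arithmetic():
    t1 = make_table("x", [0.6], [0.1])
    assert mr.mean_instrument_f(t1) == pytest.approx(36.0)
    t2 = make_table("x", [0.6, 0.8], [0.1, 0.1])
    assert mr.mean_instrument_f(t2) == pytest.approx(50.0)


def test_mean_instrument_f_matches_analytic_expectation():
    # per-variant F has expectation ~ 1 + n R^2/(1-R^2) under a fixed R^2
    from mrselect.simulate import compute_summary_stats, variant_frame

    rng = np.random.default_rng(12)
    n, J, r2 = 20_000, 60, 0.01
    maf = 0.3
    G = rng.binomial(2, maf, (n, J)).astype(float)
    b = np.sqrt(r2 / (2 * maf * (1 - maf)))
    noise_sd = np.sqrt(1 - r2)
    # J independent (variant, trait) pairs, each with the same true R^2
    Y = G * b + rng.normal(0, noise_sd, (n, J))
    fs = []
    for j in range(J):
        tab = compute_summary_stats(G[:, [j]], Y[:, j], "continuous",
                                    variant_frame(1), "t")
        fs.append(mr.mean_instrument_f(tab))
    expected = n * r2 / (1 - r2)
    assert np.mean(fs) == pytest.approx(expected, rel=0.10)


def test_cochran_q_homogeneous_and_hand_summed():
    g = np.array([0.1, 0.2, 0.4])
    hs = make_hset(g, [0.01] * 3, 0.5 * g, [0.02] * 3)
    het = mr.cochran_q(hs)
    assert het.Q == pytest.approx(0.0, abs=1e-12)
    assert het.pvalue == pytest.approx(1.0)

    G = np.array([0.06, 0.09, 0.22])
    hs2 = make_hset(g, [0.01] * 3, G, [0.02] * 3)
    theta = G / g
    w = g**2 / 0.02**2
    beta = np.sum(w * theta) / np.sum(w)
    q_hand = float(np.sum(w * (theta - beta) ** 2))
    het2 = mr.cochran_q(hs2)
    assert het2.Q == pytest.approx(q_hand, abs=1e-10)
    assert het2.Q == pytest.approx(het2.per_snp_q.sum(), abs=1e-9)
    assert het2.df == 2


# ----------------------------------------------------------- outlier removal

def test_remove_outliers_noop_on_homogeneous_set(toy_hset):
    filtered, het = mr.remove_outliers(toy_hset)
    assert het.outlier_ids == []
    assert filtered.n_variants == toy_hset.n_variants


def test_remove_outliers_catches_planted_outlier():
    rng = np.random.default_rng(21)
    L = 20
    g = rng.uniform(0.1, 0.3, L)
    Gse = np.full(L, 0.02)
    G = 0.3 * g + rng.normal(0, 0.002, L)
    # plant one instrument whose ratio sits ~10 SDs from consensus
    G[7] = 0.3 * g[7] + 10 * Gse[7]
    hs = make_hset(g, [0.01] * L, G, Gse)
    filtered, het = mr.remove_outliers(hs)
    assert het.outlier_ids == ["rs8"]
    assert filtered.n_variants == L - 1
    # Q strictly decreases after removing the planted outlier
    assert mr.cochran_q(filtered).Q < het.Q


def test_remove_outliers_matches_per_variant_chi2_rule():
    g = np.array([0.2, 0.25, 0.3])
    G = np.array([0.06, 0.075, 0.15])
    hs = make_hset(g, [0.01] * 3, G, [0.01] * 3)
    het = mr.cochran_q(hs)
    expected = [
        str(v) for v, q in zip(hs.variant_ids, het.per_snp_q)
        if stats.chi2.sf(q, 1) < 0.05 / 3
    ]
    try:
        _, het2 = mr.remove_outliers(hs)
        assert het2.outlier_ids == expected
    except mr.EstimationError:
        assert len(expected) == 3


# ------------------------------------------------------ Bonferroni and suite

def test_bonferroni_threshold_values():
    assert f"{mr.bonferroni_threshold(0.05, 13):.2g}" == "0.0038"
    assert mr.bonferroni_threshold(0.05, 1) == pytest.approx(0.05)
    assert mr.bonferroni_threshold(0.05, 5) == pytest.approx(0.01)
    with pytest.raises(mr.ConfigurationError):
        mr.bonferroni_threshold(0.05, 0)


def test_suite_consensus_gives_identical_betas(toy_hset):
    g = np.array([0.1, 0.2, 0.3, 0.15, 0.25])
    hs = make_hset(g, [0.01] * 5, 0.4 * g, [0.02] * 5)
    res = mr.run_univariable_suite(hs, mr.UnivariableConfig(n_boot=2))
    betas = {e.method: e.beta for e in res.estimates if e.method != "egger_intercept"}
    for b in betas.values():
        assert b == pytest.approx(0.4, abs=2e-3)  # mode limited by grid step


def test_suite_gates_methods_needing_three_instruments():
    hs = make_hset([0.2, 0.3], [0.01] * 2, [0.1, 0.15], [0.02] * 2)
    res = mr.run_univariable_suite(hs, mr.UnivariableConfig(n_boot=2))
    by_method = {e.method: e for e in res.estimates}
    assert by_method["ivw"].status == "ok"
    for m in ("egger", "median", "mode"):
        assert by_method[m].status == "insufficient_instruments"


def test_suite_ci_and_or_scale(toy_hset):
    res = mr.run_univariable_suite(toy_hset, mr.UnivariableConfig(n_boot=8))
    for e in res.estimates:
        if e.status != "ok":
            continue
        assert e.ci_low <= e.beta <= e.ci_high
        assert e.odds_ratio == pytest.approx(np.exp(e.beta))
        assert e.ci_low == pytest.approx(e.beta - 1.96 * e.se, abs=1e-3)
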