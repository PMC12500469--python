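"""Synthetic GWAS generator: genotypes, cohorts, scans, selection bias."""

import numpy as np
import pytest

import mrselect as mr
from mrselect.simulate import (
    _logistic_scan,
    apply_case_selection,
    compute_summary_stats,
    marginal_logodds_effects,
    simulate_cohort,
    simulate_genotypes,
    variant_frame,
)


# ----------------------------------------------------------------- genotypes

def test_genotype_means_and_variances_match_binomial_model():
    G, mafs = simulate_genotypes(5, 100_000, (0.5, 0.5), seed=1)
    assert np.allclose(G.mean(axis=0), 1.0, atol=3 * np.sqrt(0.5 / 100_000) * 3)
    G2, mafs2 = simulate_genotypes(8, 100_000, (0.1, 0.4), seed=2)
    expected_var = 2 * mafs2 * (1 - mafs2)
    assert np.allclose(G2.var(axis=0), expected_var, rtol=0.05)


def test_genotype_maf_range_validated():
    with pytest.raises(mr.ConfigurationError):
        simulate_genotypes(5, 100, (0.0, 0.4), seed=1)
    with pytest.raises(mr.ConfigurationError):
        simulate_genotypes(5, 100, (0.1, 0.6), seed=1)


# -------------------------------------------------------------------- cohort

def _basic_config(seed=0, theta=0.0, **over):
    J = over.pop("n_variants", 20)
    rng = np.random.default_rng(seed)
    return mr.SimulationConfig(
        n_variants=J, n_exposures=1,
        n_exposure_sample=over.pop("n_exposure_sample", 8000),
        n_outcome_sample=over.pop("n_outcome_sample", 8000),
        effect_matrix=rng.uniform(0.15, 0.3, (J, 1)),
        confounder_effects=np.array([0.2, 0.2]),
        causal_effects=np.array([theta]),
        seed=seed, **over,
    )


def test_exposures_are_z_standardized():
    cohort = simulate_cohort(_basic_config(1), "exposure")
    assert abs(cohort.exposures.mean()) < 1e-6
    assert cohort.exposures.std() == pytest.approx(1.0, abs=1e-6)


def test_prevalence_calibration_both_outcome_models():
    for model in ("logistic", "liability_threshold"):
        cfg = _basic_config(2, n_outcome_sample=100_000, outcome_model=model,
                            baseline_prevalence=0.1)
        cohort = simulate_cohort(cfg, "outcome")
        assert cohort.outcome.mean() == pytest.approx(0.1, abs=0.01)


def test_two_sample_cohorts_are_independent_draws():
    cfg = _basic_config(3)
    exp = simulate_cohort(cfg, "exposure")
    out = simulate_cohort(cfg, "outcome")
    assert exp.genotypes.shape[0] == cfg.n_exposure_sample
    # distinct substreams: genotype matrices differ
    assert not np.array_equal(exp.genotypes[:100], out.genotypes[:100])


def test_mediation_path_traces_through_upstream_exposure():
    # X2 has no direct variant effects; its marginal associations must equal
    # X1's scaled by the (standardized) mediation coefficient
    J, n = 20, 60_000
    rng = np.random.default_rng(4)
    B = np.zeros((J, 2))
    B[:, 0] = rng.uniform(0.15, 0.3, J)
    cfg = mr.SimulationConfig(
        n_variants=J, n_exposures=2, n_exposure_sample=n, n_outcome_sample=2000,
        effect_matrix=B, mediation_map={1: {0: 0.6}}, seed=4,
    )
    cohort = simulate_cohort(cfg, "exposure")
    t1 = compute_summary_stats(cohort.genotypes, cohort.exposures[:, 0],
                               "continuous", variant_frame(J), "x1")
    t2 = compute_summary_stats(cohort.genotypes, cohort.exposures[:, 1],
                               "continuous", variant_frame(J), "x2")
    ratio = t2.df["beta"] / t1.df["beta"]
    # X2 = 0.6 X1 + e, sd(X2_raw) = sqrt(0.36+1): slope on standardized scale
    expected = 0.6 / np.sqrt(0.36 + 1.0)
    assert ratio.mean() == pytest.approx(expected, rel=0.05)


def test_null_model_ivw_centres_on_zero():
    betas = []
    for seed in range(12):
        study = mr.make_fixture("null", 500 + seed)
        hs = mr.assemble_mvmr_set(study.exposure_tables, study.outcome_table)
        betas.append(mr.ivw(hs).beta)
    assert abs(np.mean(betas)) < 3 * np.std(betas) / np.sqrt(len(betas)) + 0.02


# ------------------------------------------------------------- summary scans

def test_noiseless_trait_recovers_construction_coefficient():
    rng = np.random.default_rng(5)
    G = rng.binomial(2, 0.3, (2000, 1)).astype(float)
    y = 0.5 * G[:, 0] + rng.normal(0, 1e-4, 2000)
    tab = compute_summary_stats(G, y, "continuous", variant_frame(1), "t")
    assert tab.df.loc[0, "beta"] == pytest.approx(0.5, abs=1e-4)
    assert tab.df.loc[0, "pvalue"] < 1e-100


def test_null_trait_type_one_error_calibrated():
    rng = np.random.default_rng(6)
    n, J = 2000, 1000
    G = rng.binomial(2, rng.uniform(0.1, 0.4, J), (n, J)).astype(float)
    y = rng.standard_normal(n)
    tab = compute_summary_stats(G, y, "continuous", variant_frame(J), "t")
    rate = (tab.df["pvalue"] < 0.05).mean()
    assert 0.03 <= rate <= 0.07


def test_logistic_scan_matches_statsmodels_irls():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(7)
    n, J = 3000, 4
    G = rng.binomial(2, 0.3, (n, J)).astype(float)
    from scipy.special import expit
    y = (rng.random(n) < expit(-1.5 + 0.3 * G[:, 0] - 0.2 * G[:, 2])).astype(float)
    beta, se, _ = _logistic_scan(G, y)
    for j in range(J):
        fit = sm.Logit(y, np.column_stack([np.ones(n), G[:, j]])).fit(disp=0)
        assert beta[j] == pytest.approx(fit.params[1], abs=1e-6)
        assert se[j] == pytest.approx(fit.bse[1], abs=1e-6)


def test_monomorphic_variant_dropped():
    rng = np.random.default_rng(8)
    G = rng.binomial(2, 0.3, (500, 3)).astype(float)
    G[:, 1] = 0.0
    y = rng.standard_normal(500)
    tab = compute_summary_stats(G, y, "continuous", variant_frame(3), "t")
    assert len(tab) == 2
    assert "snp_0002" not in set(tab.df["variant_id"])


# -------------------------------------------------------- linear -> log-odds

def test_linear_to_logodds_scaling_rules():
    b, s = mr.linear_to_logodds(0.02, 0.005, 0.5)
    assert b == pytest.approx(0.08) and s == pytest.approx(0.02)
    assert mr.linear_to_logodds(0.0, 0.01, 0.3)[0] == 0.0
    with pytest.raises(mr.ConfigurationError):
        mr.linear_to_logodds(0.1, 0.01, 0.0)


def test_linear_then_transform_agrees_with_logistic_for_common_variants():
    rng = np.random.default_rng(9)
    n, J = 40_000, 10
    G = rng.binomial(2, rng.uniform(0.2, 0.4, J), (n, J)).astype(float)
    from scipy.special import expit
    eta = G @ rng.uniform(0.05, 0.12, J) - 2.2
    y = (rng.random(n) < expit(eta)).astype(float)
    lin_b, lin_se, _ = (lambda t: (t.df["beta"].to_numpy(), t.df["se"].to_numpy(), 0))(
        compute_summary_stats(G, y, "continuous", variant_frame(J), "lin")
    )
    log_b = compute_summary_stats(G, y, "binary", variant_frame(J), "log").df["beta"].to_numpy()
    conv, _ = mr.linear_to_logodds(lin_b, lin_se, y.mean())
    assert np.all(np.abs(conv - log_b) / np.abs(log_b) < 0.10)


# ------------------------------------------------------------ case selection

def test_case_selection_zero_coefficients_is_unbiased_incident_design():
    cfg = _basic_config(10, n_outcome_sample=30_000)
    cohort = simulate_cohort(cfg, "outcome")
    sample = apply_case_selection(cohort, None, 10.0, seed=1)
    assert sample.design == "incident"
    cases_all = cohort.exposures[cohort.outcome == 1, 0]
    cases_kept = cohort.exposures[
        sample.indices[:sample.n_cases], 0
    ]
    assert cases_kept.mean() == pytest.approx(cases_all.mean(), abs=1e-12)


def test_case_selection_ratio_arithmetic():
    cfg = _basic_config(11, n_outcome_sample=30_000, baseline_prevalence=0.05)
    cohort = simulate_cohort(cfg, "outcome")
    sample = apply_case_selection(cohort, np.array([-0.5]), 10.0, seed=2)
    assert sample.design == "prevalent"
    assert sample.n_controls == min(
        10 * sample.n_cases, int((cohort.outcome == 0).sum())
    )


def test_case_selection_shifts_case_exposure_distribution():
    cfg = _basic_config(12, n_outcome_sample=50_000)
    cohort = simulate_cohort(cfg, "outcome")
    biased = apply_case_selection(cohort, np.array([-1.0]), 10.0, seed=3)
    kept_mean = cohort.exposures[biased.indices[:biased.n_cases], 0].mean()
    all_mean = cohort.exposures[cohort.outcome == 1, 0].mean()
    assert kept_mean < all_mean - 0.1  # survivors enriched for low exposure


# --------------------------------------------------------- fixtures & truth

def test_fixture_determinism_and_unknown_name():
    s1 = mr.make_fixture("null", 99)
    s2 = mr.make_fixture("null", 99)
    for t1, t2 in zip(s1.exposure_tables, s2.exposure_tables):
        assert t1.df.equals(t2.df)
    assert s1.outcome_table.df.equals(s2.outcome_table.df)
    with pytest.raises(mr.ConfigurationError):
        mr.make_fixture("nope", 1)


def test_null_fixture_truth_is_null():
    s = mr.make_fixture("null", 5)
    assert np.all(s.truth["causal_effects"] == 0)
    assert np.all(s.truth["pleiotropy"] == 0)


def test_marginal_logodds_attenuates_liability_effects():
    # non-collapsibility: marginal log-odds effects are shrunk relative to
    # the liability-scale coefficients, but only mildly at these variances
    s = mr.make_fixture("pleiotropic", 123)
    marg = s.truth["marginal_pleiotropy"]
    pleio = s.truth["pleiotropy"]
    sel = pleio > 0
    ratio = marg[sel] / pleio[sel]
    assert np.all(ratio < 1.0)
    assert np.all(ratio > 0.9)
    assert np.allclose(marg[~sel], 0.0, atol=1e-10)
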