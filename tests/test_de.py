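"""Differential-expression oracles: GLS algebra, moderation, BH, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ptbcv import (
    CONTRASTS,
    RepeatedMeasuresDE,
    SignalSpec,
    SimulationConfig,
    bh_adjust,
    estimate_consensus_correlation,
    fit_gene_models,
    moderate_variances,
    select_de_genes,
    simulate_cohort,
)
from ptbcv import test_contrasts as run_contrast_tests
from tests.conftest import make_study_from_arrays

# cell order used throughout: (term_T1, term_T2, sPTB_T1, sPTB_T2)
_CONTRAST_VECTORS = {
    "sPTB_vs_term_T1": np.array([-1.0, 0.0, 1.0, 0.0]),
    "sPTB_vs_term_T2": np.array([0.0, -1.0, 0.0, 1.0]),
    "T2_vs_T1_sPTB": np.array([0.0, 0.0, -1.0, 1.0]),
    "T2_vs_T1_term": np.array([-1.0, 1.0, 0.0, 0.0]),
    "trajectory_sPTB_vs_term": np.array([1.0, -1.0, -1.0, 1.0]),
}


def _brute_force_gls(t1, t2, is_case, rho):
    """Textbook GLS with an explicit block-diagonal correlation matrix."""
    n = len(is_case)
    # stack samples as (subj0.T1, subj0.T2, subj1.T1, ...)
    X = np.zeros((2 * n, 4))
    for j in range(n):
        base = 2 if is_case[j] else 0
        X[2 * j, base] = 1.0      # T1 cell
        X[2 * j + 1, base + 1] = 1.0  # T2 cell
    block = np.array([[1.0, rho], [rho, 1.0]])
    omega_inv = np.kron(np.eye(n), np.linalg.inv(block))
    xtx_inv = np.linalg.inv(X.T @ omega_inv @ X)
    betas, s2s = [], []
    for g in range(t1.shape[0]):
        y = np.empty(2 * n)
        y[0::2], y[1::2] = t1[g], t2[g]
        beta = xtx_inv @ X.T @ omega_inv @ y
        r = y - X @ beta
        s2s.append((r @ omega_inv @ r) / (2 * n - 4))
        betas.append(beta)
    return np.array(betas), np.array(s2s), xtx_inv


@pytest.fixture(scope="module")
def small_fit():
    rng = np.random.default_rng(7)
    n_case, n_ctrl, m = 6, 9, 12
    is_case = np.arange(n_case + n_ctrl) < n_case
    t1 = rng.normal(8.0, 1.0, size=(m, n_case + n_ctrl))
    t2 = t1 * 0.4 + rng.normal(8.0, 1.0, size=t1.shape) * 0.6
    study = make_study_from_arrays(t1, t2, is_case)
    rho = 0.4
    fits = fit_gene_models(study, study.genes, rho)
    oracle = _brute_force_gls(t1, t2, is_case, rho)
    return fits, oracle, (t1, t2, is_case)


class TestGLSOracles:
    def test_cell_means_equal_gls_estimates(self, small_fit):
        fits, (betas, _, _), _ = small_fit
        ours = fits.cell_means[["term_T1", "term_T2", "sPTB_T1", "sPTB_T2"]].to_numpy()
        np.testing.assert_allclose(ours, betas, atol=1e-10)

    def test_whitened_residual_variance_matches_matrix_form(self, small_fit):
        fits, (_, s2s, _), _ = small_fit
        np.testing.assert_allclose(fits.s2, s2s, rtol=1e-10)

    def test_contrast_variance_factors_match_matrix_form(self, small_fit):
        fits, (_, _, xtx_inv), _ = small_fit
        for j, name in enumerate(CONTRASTS):
            c = _CONTRAST_VECTORS[name]
            np.testing.assert_allclose(fits.var_factors[j], c @ xtx_inv @ c,
                                       rtol=1e-10, err_msg=name)

    def test_effects_are_contrasts_of_cell_means(self, small_fit):
        fits, (betas, _, _), _ = small_fit
        for name in CONTRASTS:
            c = _CONTRAST_VECTORS[name]
            np.testing.assert_allclose(fits.effects[name].to_numpy(),
                                       betas @ c, atol=1e-10)

    def test_rho_zero_reduces_to_ols(self):
        rng = np.random.default_rng(1)
        is_case = np.arange(10) < 4
        t1 = rng.normal(size=(5, 10))
        t2 = rng.normal(size=(5, 10))
        study = make_study_from_arrays(t1 + 8, t2 + 8, is_case)
        fits = fit_gene_models(study, study.genes, 0.0)
        # OLS pooled residual variance over the four cells
        resid = []
        for x in (t1, t2):
            for mask in (is_case, ~is_case):
                resid.append(x[:, mask] - x[:, mask].mean(axis=1, keepdims=True))
        rss = sum((r**2).sum(axis=1) for r in resid)
        np.testing.assert_allclose(fits.s2, rss / 16, rtol=1e-10)
        # paired-contrast shrinkage factor 2(1-rho) becomes plain 2/n
        np.testing.assert_allclose(fits.var_factors[2], 2.0 / 4)


class TestConsensusCorrelation:
    def test_identical_timepoints_clip_high(self):
        rng = np.random.default_rng(2)
        t1 = rng.normal(8, 1, size=(20, 12))
        study = make_study_from_arrays(t1, t1.copy(), np.arange(12) < 5)
        assert estimate_consensus_correlation(study, study.genes) == 0.99

    def test_negative_dependence_clips_to_zero(self):
        rng = np.random.default_rng(3)
        t1 = rng.normal(8, 1, size=(40, 30))
        t2 = 16 - t1 + rng.normal(0, 0.1, size=t1.shape)
        study = make_study_from_arrays(t1, t2, np.arange(30) < 10)
        assert estimate_consensus_correlation(study, study.genes) == 0.0

    def test_recovers_generator_rho(self):
        cfg = SimulationConfig(n_genes=1200, n_cases=40, n_controls=80,
                               frac_timepoint=0.0, rho_within=0.5, seed=21)
        study = simulate_cohort(cfg)
        rho = estimate_consensus_correlation(study, study.genes)
        assert abs(rho - 0.5) < 0.05


class TestModeration:
    def test_identical_variances_shrink_to_common_value(self):
        from scipy import special

        s2 = np.full(50, 2.5)
        d = 10
        res = moderate_variances(s2, d)
        assert res.d0 == pytest.approx(1e6)
        # zero spread in log s2 -> full shrinkage to the moment estimate of
        # the common variance, 2.5 * exp(log(d/2) - digamma(d/2))
        expected = 2.5 * np.exp(np.log(d / 2) - special.digamma(d / 2))
        np.testing.assert_allclose(res.s2_post, expected, rtol=1e-3)
        assert np.ptp(res.s2_post) < 1e-9

    def test_moment_recovery_of_prior(self):
        """Simulate the hierarchical model exactly and re-estimate (d0, s0^2)."""
        rng = np.random.default_rng(5)
        d0, s0_sq, d, m = 4.0, 1.0, 10, 5000
        sigma2 = d0 * s0_sq / rng.chisquare(d0, size=m)
        s2 = sigma2 * rng.chisquare(d, size=m) / d
        res = moderate_variances(s2, d)
        assert 3.0 < res.d0 < 5.0
        assert 0.9 < res.s0_sq < 1.1
        # posterior is the precision-weighted combination
        np.testing.assert_allclose(
            res.s2_post, (res.d0 * res.s0_sq + d * s2) / (res.d0 + d), rtol=1e-12)

    def test_posterior_between_prior_and_observed(self):
        rng = np.random.default_rng(6)
        s2 = np.exp(rng.normal(0, 1, size=200))
        res = moderate_variances(s2, 8)
        lo = np.minimum(s2, res.s0_sq)
        hi = np.maximum(s2, res.s0_sq)
        assert ((res.s2_post >= lo - 1e-12) & (res.s2_post <= hi + 1e-12)).all()

    def test_input_validation(self):
        with pytest.raises(ValueError):
            moderate_variances(np.array([1.0, -0.1]), 5)
        with pytest.raises(ValueError):
            moderate_variances(np.array([1.0, 2.0]), 0)


class TestBH:
    def test_worked_example(self):
        p = np.array([0.01, 0.04, 0.03, 0.005])
        # sorted: .005*4/1=.02, .01*4/2=.02, .03*4/3=.04, .04*4/4=.04
        np.testing.assert_allclose(bh_adjust(p), [0.02, 0.04, 0.04, 0.02])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_matches_reference_implementation(self, p):
        p = np.array(p)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_monotone_in_input_order_of_ranks(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=500)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))
        with pytest.raises(ValueError):
            bh_adjust(np.array([[0.1, 0.2]]))


class TestEndToEnd:
    def test_null_moderated_p_uniform(self):
        """On outcome-null data the T1 contrast p-values are uniform."""
        cfg = SimulationConfig(n_genes=1500, n_cases=30, n_controls=30,
                               frac_low_variance=0.0, frac_high_variance=0.0,
                               frac_low_expression=0.0, frac_timepoint=0.0,
                               seed=30)
        study = simulate_cohort(cfg)
        res = RepeatedMeasuresDE(study).fit()
        tab = res.table.table
        p = tab.loc[tab["contrast"] == "sPTB_vs_term_T1", "p"].to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_planted_trajectory_signal_detected(self):
        cfg = SimulationConfig(
            n_genes=600, n_cases=49, n_controls=114,
            baseline_mean_range=(7.0, 12.0),  # keep planted genes above the expression floor
            gene_sd_range=(0.4, 0.7), frac_timepoint=0.0,
            signals=[SignalSpec("trajectory_diff", 8, 1.5)], seed=31)
        study = simulate_cohort(cfg)
        res = RepeatedMeasuresDE(study).fit()
        planted = {g for g, _ in study.truth}
        assert planted <= set(res.de_genes)
        tab = res.table.table
        traj = tab[(tab["contrast"] == "trajectory_sPTB_vs_term")
                   & tab["gene"].isin(planted)]
        assert (traj["p_adj"] < 1e-4).all()

    def test_pooled_adjustment_is_single_family(self):
        cfg = SimulationConfig(n_genes=200, n_cases=12, n_controls=12,
                               frac_timepoint=0.0, seed=32)
        study = simulate_cohort(cfg)
        rho = estimate_consensus_correlation(study, study.genes)
        fits = fit_gene_models(study, study.genes, rho)
        mod = moderate_variances(fits.s2, fits.df_resid)
        pooled = run_contrast_tests(fits, mod, adjust="pooled")
        expected = bh_adjust(pooled.table["p"].to_numpy())
        np.testing.assert_allclose(pooled.table["p_adj"].to_numpy(), expected)

    def test_de_gene_list_deduplicated_and_thresholded(self):
        cfg = SimulationConfig(n_genes=300, n_cases=20, n_controls=20,
                               signals=[SignalSpec("T2_diff", 5, 2.0)], seed=33)
        study = simulate_cohort(cfg)
        res = RepeatedMeasuresDE(study).fit()
        genes = select_de_genes(res.table, alpha=0.05)
        assert len(genes) == len(set(genes))
        tab = res.table.table
        hand = set(tab.loc[tab["p_adj"] < 0.05, "gene"])
        assert set(genes) == hand
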