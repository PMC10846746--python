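import numpy as np
import pytest

from renalrec.cohort import generate_cohort, toy_config
from renalrec.design import recover_beta
from renalrec.model import (CovarianceStructure, ModelSpec, SamplerConfig,
                            correlation_blocks, fit,
                            posterior_predictive_check, predict_mu,
                            summarize_effects)
from renalrec.transforms import corr_chol_forward, n_corr_params

from conftest import FAST_SAMPLER


class TestModelSpec:
    def test_rejects_unknown_variant(self):
        with pytest.raises(ValueError, match="variant"):
            ModelSpec(variant="three_level")

    def test_prior_defaults_merged(self):
        spec = ModelSpec(priors={"beta_scale": 2.0})
        assert spec.priors["beta_scale"] == 2.0
        assert spec.priors["lkj_eta"] == 2.0


class TestCovarianceStructure:
    def test_valid_structure(self):
        L, _ = corr_chol_forward(np.array([0.3, -0.2, 0.5]), 3)
        cs = CovarianceStructure(sigma=np.array([1.0, 2.0, 0.5]),
                                 L_corr=L, level="personal")
        C = cs.corr
        np.testing.assert_allclose(np.diag(C), 1.0)
        np.testing.assert_allclose(np.diag(cs.cov),
                                   np.array([1.0, 4.0, 0.25]))

    def test_rejects_nonunit_rows(self):
        with pytest.raises(ValueError, match="unit norm"):
            CovarianceStructure(sigma=np.ones(2),
                                L_corr=np.array([[1.0, 0.0], [0.5, 0.5]]),
                                level="treatment")

    def test_correlation_blocks_assemble(self):
        p, M = 2, 3
        L, _ = corr_chol_forward(
            np.random.default_rng(0).standard_normal(n_corr_params(p * M)),
            p * M)
        C = L @ L.T
        within, cross = correlation_blocks(C, p, M)
        assert len(within) == M
        for (n, m), block in cross.items():
            np.testing.assert_allclose(block, cross[(m, n)].T)
        rebuilt = np.block([
            [within[n] if n == m else cross[(n, m)] for m in range(M)]
            for n in range(M)])
        np.testing.assert_allclose(rebuilt, C)


class TestFittedPosterior:
    def test_beta_consistent_with_qr_recovery(self, fitted):
        """beta_std draws equal R*^-1 beta* draw by draw."""
        _, post = fitted
        bstar = post.stacked("beta_star")
        bstd = post.stacked("beta_std")
        for s in range(0, bstar.shape[0], 100):
            np.testing.assert_allclose(
                recover_beta(bstar[s], post.qr), bstd[s], atol=1e-10)

    def test_qr_predictions_equal_direct_predictions(self, fitted):
        data, post = fitted
        Xs = post.standardizer.transform(data.x_matrix())
        bstar = post.stacked("beta_star")
        bstd = post.stacked("beta_std")
        for s in (0, 50):
            np.testing.assert_allclose(post.qr.Q_star @ bstar[s],
                                       Xs @ bstd[s], atol=1e-8)

    def test_correlation_cholesky_valid_on_every_draw(self, fitted):
        _, post = fitted
        for name in ("L_g", "L_b"):
            Ls = post.stacked(name)
            sub = Ls[:: max(1, len(Ls) // 50)]
            for L in sub:
                C = L @ L.T
                np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-8)
                assert np.linalg.eigvalsh(C).min() > -1e-10

    def test_diagnostics_reported(self, fitted):
        _, post = fitted
        d = post.diagnostics
        assert {"parameter", "ess", "rhat"} <= set(d.columns)
        assert (d["ess"] > 0).all()

    def test_seed_reproducibility(self, toy_cohort):
        _, data, _ = toy_cohort
        cfgs = SamplerConfig(chains=1, draws=30, warmup=30, seed=3,
                             **FAST_SAMPLER)
        p1 = fit(data, ModelSpec(), cfgs)
        p2 = fit(data, ModelSpec(), cfgs)
        np.testing.assert_array_equal(p1.stacked("beta"), p2.stacked("beta"))


class TestVariants:
    def test_separate_univariate_has_no_cross_correlations(self, toy_cohort):
        _, data, _ = toy_cohort
        post = fit(data, ModelSpec(variant="separate_univariate"),
                   SamplerConfig(chains=1, draws=40, warmup=40, seed=1,
                                 **FAST_SAMPLER))
        p = len(post.predictor_names)
        M = len(post.response_names)
        L_b = post.stacked("L_b")
        # cross-response blocks are structurally zero in every draw
        for m in range(M):
            for n in range(M):
                if m == n:
                    continue
                blk = L_b[:, m * p:(m + 1) * p, n * p:(n + 1) * p]
                assert np.all(blk == 0)

    def test_single_level_omits_treatment_draws(self, toy_cohort):
        _, data, _ = toy_cohort
        post = fit(data, ModelSpec(variant="single_level"),
                   SamplerConfig(chains=1, draws=40, warmup=40, seed=1,
                                 **FAST_SAMPLER))
        assert "g" not in post.draws
        assert "sigma_g" not in post.draws

    def test_response_subset(self, toy_cohort):
        _, data, _ = toy_cohort
        post = fit(data, ModelSpec(variant="single_level",
                                   responses=["p_k", "fp_pi"]),
                   SamplerConfig(chains=1, draws=30, warmup=30, seed=1,
                                 **FAST_SAMPLER))
        assert post.response_names == ["p_k", "fp_pi"]
        assert post.stacked("beta").shape[2] == 2


class TestSummaries:
    def test_degenerate_draws_give_point_interval(self, fitted):
        _, post = fitted
        import copy
        clone = copy.copy(post)
        clone.draws = dict(post.draws)
        const = np.full_like(post.draws["beta"], 1.25)
        clone.draws["beta"] = const
        clone.draws["sigma_g"] = np.zeros_like(post.draws["sigma_g"])
        table = summarize_effects(clone, level="general")
        assert np.allclose(table["mean"], 1.25)
        assert np.allclose(table["q0.050"], 1.25)
        assert np.allclose(table["q0.950"], 1.25)

    def test_treatment_rows_equal_general_when_g_zero(self, fitted):
        _, post = fitted
        import copy
        clone = copy.copy(post)
        clone.draws = dict(post.draws)
        clone.draws["g"] = np.zeros_like(post.draws["g"])
        gen = summarize_effects(clone, level="general")
        tre = summarize_effects(clone, level="treatment")
        for t in np.unique(tre["treatment"]):
            sub = tre[tre["treatment"] == t]
            np.testing.assert_allclose(sub["mean"].to_numpy(),
                                       gen["mean"].to_numpy(), atol=1e-12)

    def test_quantiles_match_order_statistics_oracle(self, fitted):
        _, post = fitted
        import copy
        clone = copy.copy(post)
        clone.draws = dict(post.draws)
        # hand-written 10-draw posterior for one coefficient
        vals = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.0, 6.0, 5.0, 3.5, 7.0])
        beta = np.zeros((1, 10) + post.draws["beta"].shape[2:])
        beta[0, :, 0, 0] = vals
        clone.draws["beta"] = beta
        clone.draws["sigma_g"] = np.zeros((1, 10)
                                          + post.draws["sigma_g"].shape[2:])
        table = summarize_effects(clone, level="general")
        row = table[(table["predictor"] == post.predictor_names[0])
                    & (table["response"] == post.response_names[0])]
        assert row["mean"].iloc[0] == pytest.approx(vals.mean())
        assert row["q0.050"].iloc[0] == pytest.approx(
            np.quantile(vals, 0.05))
        assert row["q0.950"].iloc[0] == pytest.approx(
            np.quantile(vals, 0.95))

    def test_unknown_level_rejected(self, fitted):
        _, post = fitted
        with pytest.raises(ValueError, match="level"):
            summarize_effects(post, level="cosmic")


class TestPPC:
    def test_self_consistency_bias_small(self, fitted):
        data, post = fitted
        rep = posterior_predictive_check(post, data, n_rep=150, seed=0)
        assert rep.aligned(n_se=3.0), (rep.bias, rep.rep_sd)

    def test_masked_cells_excluded(self, fitted_masked):
        data, post, _, _ = fitted_masked
        rep = posterior_predictive_check(post, data, n_rep=50, seed=0)
        # observed mean computed over unmasked cells only
        y = data.y_matrix()
        mask = data.mask()
        alb = data.response_names.index("p_alb")
        expected = y[mask[:, alb], alb].mean()
        assert rep.observed_mean[alb] == pytest.approx(expected)


def test_shift_invariance_of_predictive_means(toy_cohort):
    """Refitting with a larger shift changes the parameterization but not the
    predicted concentrations (within Monte-Carlo error)."""
    _, data, _ = toy_cohort
    mus = []
    for shift in (None, 40.0):
        post = fit(data, ModelSpec(shift_c=shift),
                   SamplerConfig(chains=1, draws=150, warmup=150, seed=9,
                                 **FAST_SAMPLER))
        mus.append(predict_mu(post, data))
    scale = np.abs(mus[0]).mean()
    assert np.abs(mus[0] - mus[1]).mean() / scale < 0.05


def test_variant_nesting_likelihood_equivalence(toy_cohort):
    """With treatment deviations pinned to zero, the two-level model's mean
    surface (hence its likelihood) coincides with the single-level model's
    on identical remaining parameters."""
    from renalrec.model import _HierPosterior
    _, data, _ = toy_cohort
    po2 = _HierPosterior(data, ModelSpec(variant="two_level"))
    po1 = _HierPosterior(data, ModelSpec(variant="single_level"))
    rng = np.random.default_rng(0)
    th1 = po1.initial_point(rng) + 0.1 * rng.standard_normal(po1.n_params)
    th2 = np.zeros(po2.n_params)
    for name in ("bstar", "a", "zb", "lsb", "yb", "la"):
        th2[po2.slices[name]] = th1[po1.slices[name]]
    # zg = 0 by construction
    mu1, _ = po1._mu(po1.unpack(th1))
    mu2, _ = po2._mu(po2.unpack(th2))
    np.testing.assert_allclose(mu1, mu2, atol=1e-12)


def test_single_level_posterior_agrees_with_glm_oracle():
    """M=1, p=1, no hierarchy: the posterior mean of the general effect is
    consistent (within 2 posterior sd) with a gamma GLM fitted by maximum
    likelihood with an identity link on the shifted response."""
    import statsmodels.api as sm

    cfg = toy_config(K=6, L=1, sizes=(6,), n_obs=10, p=1, M=1,
                     sigma_frac_g=0.0, sigma_frac_b=0.0, alpha=80.0, seed=21,
                     beta_seed=22)
    data, truth = generate_cohort(cfg)
    shift = 2.0 * float(np.abs(data.y_matrix()).max())
    post = fit(data, ModelSpec(variant="single_level", shift_c=shift),
               SamplerConfig(chains=1, draws=300, warmup=250, seed=13,
                             **FAST_SAMPLER))
    x = data.x_matrix()[:, 0]
    y = data.y_matrix()[:, 0] + shift
    glm = sm.GLM(y, sm.add_constant(x),
                 family=sm.families.Gamma(sm.families.links.Identity()))
    res = glm.fit()
    beta_mle = res.params[1]
    beta_draws = post.stacked("beta")[:, 0, 0]
    sd = beta_draws.std(ddof=1)
    assert abs(beta_draws.mean() - beta_mle) < 2 * sd
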