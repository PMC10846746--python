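import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from renalrec.graph import IntakeDistribution, NormalRanges, PersonalGraph
from renalrec.recommend import (RecommendationQuery, baseline_mu, confidence,
                                recommend, recommend_grid_oracle,
                                sampling_limits, sensitivity)


def make_graph(effects, intercept, alpha, ranges, shift_c=0.0,
               intake_mean=None, intake_sd=None, names=None, resp=None):
    """Deterministic single-draw graph for closed-form recommendation tests.

    ``effects``: (M, p) point effects.
    """
    effects = np.asarray(effects, float)
    M, p = effects.shape
    names = names or [f"x{j}" for j in range(p)]
    resp = resp or [f"y{m}" for m in range(M)]
    mean = np.asarray(intake_mean if intake_mean is not None
                      else np.full(p, 1.0), float)
    sd = np.asarray(intake_sd if intake_sd is not None
                    else np.full(p, 0.1), float)
    intakes = IntakeDistribution(patient=0, names=names, mean=mean, sd=sd,
                                 n_obs=2)
    return PersonalGraph(
        patient=0, treatment=0, intakes=intakes,
        effect_draws=effects[None, :, :],
        intercept_draws=np.asarray(intercept, float)[None, :],
        alpha_draws=np.asarray(alpha, float)[None, :],
        shift_c=shift_c, ranges=ranges,
        predictor_names=names, response_names=resp)


class TestBaselineMu:
    def test_hand_computed(self):
        g = make_graph([[0.5, 1.0, 2.0]], [0.0], [100.0],
                       NormalRanges({"y0": 0.0}, {"y0": 100.0}),
                       intake_mean=[1.0, 2.0, 4.0])
        q = RecommendationQuery(queried=["x2"],
                                proposal_bounds={"x2": (0.0, 10.0)}, S=10)
        np.testing.assert_allclose(baseline_mu(g, q), [2.5])

    def test_all_queried_leaves_intercept(self):
        g = make_graph([[0.5, 1.0]], [3.0], [100.0],
                       NormalRanges({"y0": 0.0}, {"y0": 100.0}))
        q = RecommendationQuery(
            queried=["x0", "x1"],
            proposal_bounds={"x0": (0, 1), "x1": (0, 1)}, S=10)
        np.testing.assert_allclose(baseline_mu(g, q), [3.0])

    def test_empty_query_is_full_prediction(self):
        g = make_graph([[0.5, 1.0]], [3.0], [100.0],
                       NormalRanges({"y0": 0.0}, {"y0": 100.0}),
                       intake_mean=[2.0, 1.0])
        q = RecommendationQuery(queried=[], proposal_bounds={}, S=10)
        np.testing.assert_allclose(baseline_mu(g, q), [3.0 + 1.0 + 1.0])

    def test_unknown_nutrient_rejected(self):
        g = make_graph([[0.5]], [0.0], [100.0],
                       NormalRanges({"y0": 0.0}, {"y0": 1.0}))
        q = RecommendationQuery(queried=["nope"],
                                proposal_bounds={"nope": (0, 1)}, S=10)
        with pytest.raises(ValueError, match="nope"):
            baseline_mu(g, q)


class TestSamplingLimits:
    def test_baseline_inside_range(self):
        assert sampling_limits(5.0, 3.0, 8.0) == (3.0, 8.0)

    def test_baseline_below_lower(self):
        assert sampling_limits(-2.0, 3.0, 8.0) == (-2.0, 8.0)

    def test_baseline_above_upper(self):
        assert sampling_limits(13.0, 3.0, 8.0) == (3.0, 13.0)

    def test_degenerate_range(self):
        with pytest.raises(ValueError):
            sampling_limits(1.0, 5.0, 5.0)


class TestConfidence:
    def test_full_support_is_one(self):
        assert confidence(5.0, 10.0, 0.0, np.inf, 0.0) == pytest.approx(1.0)

    def test_concentrates_with_large_alpha(self):
        lo, hi = 4.9, 5.1
        small = confidence(5.0, 10.0, lo, hi, 0.0)
        large = confidence(5.0, 1e6, lo, hi, 0.0)
        assert large > 0.999 and large > small

    def test_matches_quadrature(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            mu = rng.uniform(1, 20)
            alpha = rng.uniform(2, 300)
            c = rng.uniform(0, 10)
            lo = mu * rng.uniform(0.3, 0.9)
            hi = lo + mu * rng.uniform(0.1, 1.0)
            ref = quad(lambda t: stats.gamma.pdf(t, alpha,
                                                 scale=(mu + c) / alpha),
                       lo + c, hi + c, epsabs=1e-12)[0]
            assert abs(confidence(mu, alpha, lo, hi, c) - ref) < 1e-8

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            confidence(5.0, 10.0, 3.0, 3.0, 0.0)
        with pytest.raises(ValueError):
            confidence(-10.0, 10.0, 1.0, 2.0, 0.0)


def unconstrained_graph():
    return make_graph([[0.1], [0.2]], [1.0, 2.0], [50.0, 50.0],
                      NormalRanges({"y0": -np.inf, "y1": -np.inf},
                                   {"y0": np.inf, "y1": np.inf}),
                      resp=["y0", "y1"])


class TestRecommend:
    def test_unconstrained_accepts_everything(self):
        g = unconstrained_graph()
        q = RecommendationQuery(queried=["x0"],
                                proposal_bounds={"x0": (0.0, 10.0)},
                                S=4000, conf_level=0.5, seed=1)
        res = recommend(g, q)
        assert res.succeeded
        assert len(res.accepted) == 4000
        assert res.q_min[0] == pytest.approx(0.25, abs=0.15)
        assert res.q_max[0] == pytest.approx(9.75, abs=0.15)

    def test_zero_effect_failure_reports_baseline_confidence(self):
        # queried nutrient has no effect and the baseline sits far outside
        ranges = NormalRanges({"y0": 50.0}, {"y0": 60.0})
        g = make_graph([[0.0]], [5.0], [100.0], ranges)
        q = RecommendationQuery(queried=["x0"],
                                proposal_bounds={"x0": (0.0, 10.0)},
                                S=500, conf_level=0.9, seed=2)
        res = recommend(g, q)
        assert not res.succeeded
        base_conf = confidence(5.0, 100.0, 50.0, 60.0, 0.0)
        assert res.p_max == pytest.approx(base_conf, abs=1e-12)
        assert np.isnan(res.q_min[0])

    def test_s_zero_rejected(self):
        g = unconstrained_graph()
        q = RecommendationQuery(queried=["x0"],
                                proposal_bounds={"x0": (0.0, 1.0)}, S=0)
        with pytest.raises(ValueError):
            recommend(g, q)

    def test_deterministic_under_seed(self):
        g = unconstrained_graph()
        q = RecommendationQuery(queried=["x0"],
                                proposal_bounds={"x0": (0.0, 10.0)},
                                S=200, conf_level=0.5, seed=5)
        r1, r2 = recommend(g, q), recommend(g, q)
        np.testing.assert_array_equal(r1.samples, r2.samples)
        np.testing.assert_array_equal(r1.confidences, r2.confidences)

    def test_failure_honesty(self):
        # reachable sampling region but confidence everywhere below target
        ranges = NormalRanges({"y0": 4.9}, {"y0": 5.1})
        g = make_graph([[0.1]], [4.0], [30.0], ranges)
        q = RecommendationQuery(queried=["x0"],
                                proposal_bounds={"x0": (0.0, 20.0)},
                                S=2000, conf_level=0.9, seed=3)
        res = recommend(g, q)
        if not res.succeeded:
            assert res.p_max < 0.9
            assert res.p_max == pytest.approx(res.confidences.max())


class TestGridOracleAgreement:
    def grid_vs_sampler(self, effects, intercept, alpha, lo, hi, bounds,
                        conf, seed, shift_c=0.0):
        M = len(intercept)
        resp = [f"y{m}" for m in range(M)]
        ranges = NormalRanges(dict(zip(resp, lo)), dict(zip(resp, hi)))
        g = make_graph(effects, intercept, alpha, ranges, shift_c=shift_c,
                       resp=resp)
        queried = [f"x{j}" for j in range(np.asarray(effects).shape[1])]
        q = RecommendationQuery(queried=queried,
                                proposal_bounds=dict(zip(queried, bounds)),
                                S=6000, conf_level=conf, seed=seed)
        res = recommend(g, q)
        oracle = recommend_grid_oracle(g, q, grid_points=250 if M == 1
                                       else 120)
        return res, oracle, bounds

    def test_1d_agreement(self):
        res, oracle, bounds = self.grid_vs_sampler(
            [[0.3]], [2.0], [200.0], [4.0], [7.0], [(0.0, 20.0)], 0.8, 11)
        width = bounds[0][1] - bounds[0][0]
        assert res.succeeded == oracle.succeeded
        if res.succeeded:
            assert abs(res.q_min[0] - oracle.q_min[0]) < 0.02 * width
            assert abs(res.q_max[0] - oracle.q_max[0]) < 0.02 * width

    def test_2d_agreement(self):
        res, oracle, bounds = self.grid_vs_sampler(
            [[0.3, -0.1], [0.05, 0.25]], [2.0, 1.0], [300.0, 300.0],
            [4.0, 2.0], [7.0, 4.0], [(0.0, 20.0), (0.0, 15.0)], 0.8, 12)
        assert res.succeeded == oracle.succeeded
        if res.succeeded:
            for r in range(2):
                width = bounds[r][1] - bounds[r][0]
                assert abs(res.q_min[r] - oracle.q_min[r]) < 0.03 * width
                assert abs(res.q_max[r] - oracle.q_max[r]) < 0.03 * width

    def test_consistent_failure_on_impossible_targets(self):
        res, oracle, _ = self.grid_vs_sampler(
            [[0.01]], [2.0], [50.0], [40.0], [41.0], [(0.0, 5.0)], 0.99, 13)
        assert not res.succeeded and not oracle.succeeded

    def test_monotone_acceptance_is_interval(self):
        # single response with positive effect: confidence is unimodal in q,
        # so the accepted grid region is a contiguous interval
        ranges = NormalRanges({"y0": 4.0}, {"y0": 7.0})
        g = make_graph([[0.3]], [2.0], [400.0], ranges)
        q = RecommendationQuery(queried=["x0"],
                                proposal_bounds={"x0": (0.0, 25.0)},
                                S=100, conf_level=0.8, seed=1)
        oracle = recommend_grid_oracle(g, q, grid_points=400)
        acc = oracle.confidences > 0.8
        if acc.any():
            idx = np.flatnonzero(acc)
            assert np.all(np.diff(idx) == 1)

    def test_r3_rejected(self):
        g = make_graph([[0.1, 0.1, 0.1]], [1.0], [50.0],
                       NormalRanges({"y0": 0.0}, {"y0": 10.0}))
        q = RecommendationQuery(
            queried=["x0", "x1", "x2"],
            proposal_bounds={n: (0.0, 1.0) for n in ("x0", "x1", "x2")},
            S=10)
        with pytest.raises(ValueError, match="at most 2"):
            recommend_grid_oracle(g, q)


class TestThresholdMonotonicity:
    def test_higher_confidence_narrows_bounds(self):
        ranges = NormalRanges({"y0": 4.0}, {"y0": 7.0})
        g = make_graph([[0.3]], [2.0], [150.0], ranges)
        qs = {}
        for c in (0.8, 0.9):
            q = RecommendationQuery(queried=["x0"],
                                    proposal_bounds={"x0": (0.0, 25.0)},
                                    S=5000, conf_level=c, seed=21)
            qs[c] = recommend(g, q)
        if qs[0.9].succeeded:
            assert qs[0.8].succeeded
            assert qs[0.9].q_min[0] >= qs[0.8].q_min[0] - 1e-9
            assert qs[0.9].q_max[0] <= qs[0.8].q_max[0] + 1e-9
            # acceptance sets nest exactly on the shared sample cloud
            acc8 = qs[0.8].confidences > 0.8
            acc9 = qs[0.9].confidences > 0.9
            assert np.all(acc9 <= acc8)


class TestSensitivity:
    def degenerate_graph(self):
        # single-draw posterior -> quantiles of effects coincide
        return make_graph([[0.2]], [2.0], [200.0],
                          NormalRanges({"y0": 3.0}, {"y0": 6.0}))

    def test_degenerate_posterior_identical_across_quantiles(self):
        g = self.degenerate_graph()
        g.intakes.sd = np.full(1, 1e-12)
        q = RecommendationQuery(queried=["x0"],
                                proposal_bounds={"x0": (0.0, 20.0)},
                                S=2000, seed=3)
        results = sensitivity(g, q, conf_levels=(0.8,))
        vals = [(np.round(r.q_min, 3).tolist(), np.round(r.q_max, 3).tolist())
                for _, r in results]
        assert vals.count(vals[0]) == len(vals)

    def test_wide_effect_posterior_tail_runs_accept_fewer(self):
        rng = np.random.default_rng(4)
        eff = 0.2 + 0.15 * rng.standard_normal((400, 1, 1))
        g = make_graph([[0.2]], [2.0], [200.0],
                       NormalRanges({"y0": 3.0}, {"y0": 6.0}))
        g.effect_draws = eff
        g.intercept_draws = np.tile(g.intercept_draws, (400, 1))
        g.alpha_draws = np.tile(g.alpha_draws, (400, 1))
        q = RecommendationQuery(queried=["x0"],
                                proposal_bounds={"x0": (0.0, 20.0)},
                                S=3000, conf_level=0.8, seed=5)
        from dataclasses import replace
        mid = recommend(g, replace(q, l_beta=0.5))
        lo = recommend(g, replace(q, l_beta=0.05))
        hi = recommend(g, replace(q, l_beta=0.95))
        assert len(lo.accepted) <= len(mid.accepted)
        assert len(hi.accepted) <= len(mid.accepted)
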