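import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import gammaln

from storknet import synthdata, vergm


def small_model(n=5, seed=0, terms=None):
    rng = np.random.default_rng(seed)
    habs = ["Landfills", "Marshes", "Rice fields", "Urban areas", "Marshes"][:n]
    D = synthdata.random_distance_matrix(n, rng, 1.0, 30.0)
    terms = terms or ["sum", "nodeofactor:Landfills", "nodeifactor:Marshes", "edgecov:distance_km", "mutuality"]
    return vergm.ErgmModel(terms, habs, {"distance_km": D})


def brute_stats(y, model):
    """Independent double-loop implementation of the sufficient statistics."""
    n = model.n
    out = []
    for t in model.terms:
        total = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if t.kind == "sum":
                    total += y[i, j]
                elif t.kind == "nodeofactor":
                    total += y[i, j] * (model.habitats[i] == t.arg)
                elif t.kind == "nodeifactor":
                    total += y[i, j] * (model.habitats[j] == t.arg)
                elif t.kind == "edgecov":
                    total += y[i, j] * model.covariates[t.arg][i, j]
        if t.kind == "mutuality":
            total = -sum(
                abs(y[i, j] - y[j, i]) for i in range(n) for j in range(i + 1, n)
            )
        out.append(total)
    return np.array(out)


class TestSufficientStats:
    def test_empty_network_all_zero(self):
        model = small_model()
        np.testing.assert_array_equal(model.sufficient_stats(np.zeros((5, 5))), 0.0)

    def test_hand_arithmetic_two_nodes(self):
        D = np.array([[0.0, 2.0], [2.0, 0.0]])
        model = vergm.ErgmModel(
            ["sum", "nodeofactor:Landfills", "nodeifactor:Marshes", "edgecov:distance_km", "mutuality"],
            ["Landfills", "Marshes"],
            {"distance_km": D},
        )
        y = np.array([[0, 3], [1, 0]])
        g = model.sufficient_stats(y)
        np.testing.assert_allclose(g, [4.0, 3.0, 3.0, 8.0, -2.0])

    def test_matches_double_loop_oracle_on_random_networks(self):
        rng = np.random.default_rng(1)
        model = small_model(seed=3)
        for _ in range(10):
            y = rng.integers(0, 7, size=(5, 5))
            np.fill_diagonal(y, 0)
            np.testing.assert_allclose(model.sufficient_stats(y), brute_stats(y, model))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_mutuality_nonpositive_zero_iff_reciprocal(self, seed):
        rng = np.random.default_rng(seed)
        model = small_model(terms=["sum", "mutuality"])
        y = rng.integers(0, 5, size=(5, 5))
        np.fill_diagonal(y, 0)
        g_mut = model.sufficient_stats(y)[1]
        assert g_mut <= 0
        assert (g_mut == 0) == bool(np.all(y == y.T))

    def test_duplicate_statistic_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            small_model(terms=["sum", "sum"])

    def test_missing_factor_level_rejected(self):
        with pytest.raises(ValueError, match="Dams"):
            small_model(terms=["sum", "nodeifactor:Dams"])


class TestLinearPredictor:
    def test_zero_theta(self):
        model = small_model()
        assert vergm.dyad_linear_predictor(0, 1, np.zeros(model.k), model) == 0.0

    def test_landfill_out_effect_adds_up(self):
        D = np.zeros((2, 2))
        model = vergm.ErgmModel(
            ["sum", "nodeofactor:Landfills", "edgecov:distance_km"],
            ["Landfills", "Urban areas"],
            {"distance_km": D},
        )
        theta = np.array([4.75, 1.49, -0.15])
        assert vergm.dyad_linear_predictor(0, 1, theta, model) == pytest.approx(6.24)
        assert vergm.dyad_linear_predictor(1, 0, theta, model) == pytest.approx(4.75)

    def test_distance_linearity(self):
        D = np.array([[0.0, 10.0], [10.0, 0.0]])
        model = vergm.ErgmModel(["sum", "edgecov:distance_km"], ["Landfills", "Marshes"], {"distance_km": D})
        eta0 = vergm.dyad_linear_predictor(0, 1, np.array([1.0, 0.0]), model)
        eta1 = vergm.dyad_linear_predictor(0, 1, np.array([1.0, -0.15]), model)
        assert eta1 - eta0 == pytest.approx(-1.5)


class TestDyadLogPartition:
    def test_zero_theta_gives_two(self):
        logZ, _cap = vergm.dyad_log_partition(0.0, 0.0, 0.0)
        assert logZ == pytest.approx(2.0, abs=1e-12)

    def test_no_mutuality_closed_form(self):
        for e1, e2 in [(0.3, -1.0), (2.0, 2.0), (-4.0, 1.5)]:
            logZ, _ = vergm.dyad_log_partition(e1, e2, 0.0)
            assert logZ == pytest.approx(np.exp(e1) + np.exp(e2), rel=1e-12)

    def test_matches_high_cap_double_sum(self):
        a = np.arange(201)
        for e1, e2, tm in [(0.5, 0.5, 0.3), (1.0, -0.5, -0.6), (2.0, 1.5, 1.2)]:
            L = e1 * a[:, None] + e2 * a[None, :] - tm * np.abs(a[:, None] - a[None, :])
            L = L - gammaln(a + 1)[:, None] - gammaln(a + 1)[None, :]
            want = math.log(np.exp(L - L.max()).sum()) + L.max()
            got, _ = vergm.dyad_log_partition(e1, e2, tm)
            assert got == pytest.approx(want, rel=1e-10)


class TestLikelihood:
    def test_theta_zero_empty_network(self):
        model = small_model(terms=["sum", "mutuality"])
        y = np.zeros((5, 5), dtype=int)
        ell, _ = vergm.loglik_and_gradient(np.zeros(2), y, model)
        assert ell == pytest.approx(-2.0 * 10, rel=1e-12)  # -2 per dyad, 10 dyads

    def test_gradient_matches_central_differences(self):
        model = small_model(seed=5)
        rng = np.random.default_rng(2)
        y = rng.integers(0, 6, size=(5, 5))
        np.fill_diagonal(y, 0)
        theta = np.array([0.4, 0.3, -0.2, -0.05, 0.35])
        _, grad = vergm.loglik_and_gradient(theta, y, model)
        for k in range(len(theta)):
            h = 1e-6
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            fd = (
                vergm.loglik_and_gradient(tp, y, model)[0] - vergm.loglik_and_gradient(tm, y, model)[0]
            ) / (2 * h)
            assert grad[k] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_hessian_matches_gradient_differences(self):
        model = small_model(seed=5)
        rng = np.random.default_rng(3)
        y = rng.integers(0, 6, size=(5, 5))
        np.fill_diagonal(y, 0)
        theta = np.array([0.4, 0.3, -0.2, -0.05, 0.35])
        _, _, H = vergm.loglik_grad_hessian(theta, y, model)
        for k in range(len(theta)):
            h = 1e-6
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            col = (
                vergm.loglik_and_gradient(tp, y, model)[1] - vergm.loglik_and_gradient(tm, y, model)[1]
            ) / (2 * h)
            np.testing.assert_allclose(H[:, k], col, rtol=1e-4, atol=1e-5)

    def test_gradient_vanishes_at_mle(self):
        model = small_model(seed=7)
        y = vergm.simulate_network(np.array([1.0, 0.5, -0.3, -0.1, 0.4]), model, seed=4)
        fit = vergm.fit_mle(y, model)
        _, grad = vergm.loglik_and_gradient(fit.theta, y, model)
        scale = np.maximum(1.0, np.abs(model.sufficient_stats(y)))
        assert np.max(np.abs(grad) / scale) < 1e-6

    def test_concave_along_random_sections(self):
        model = small_model(seed=9)
        rng = np.random.default_rng(5)
        y = rng.integers(0, 5, size=(5, 5))
        np.fill_diagonal(y, 0)
        theta0 = rng.normal(0, 0.3, model.k)
        direction = rng.normal(0, 0.2, model.k)
        ts = np.linspace(-1, 1, 9)
        vals = [vergm.loglik_and_gradient(theta0 + t * direction, y, model)[0] for t in ts]
        second = np.diff(vals, 2)
        assert (second <= 1e-8).all()


class TestFitMle:
    def test_sum_only_mle_is_log_mean_count(self):
        model = small_model(terms=["sum"])
        rng = np.random.default_rng(0)
        y = rng.integers(0, 9, size=(5, 5))
        np.fill_diagonal(y, 0)
        fit = vergm.fit_mle(y, model)
        mean_count = y[~np.eye(5, dtype=bool)].mean()
        assert fit.theta[0] == pytest.approx(math.log(mean_count), abs=1e-8)

    def test_matches_statsmodels_poisson_glm_without_mutuality(self):
        sm = pytest.importorskip("statsmodels.api")
        model = small_model(terms=["sum", "nodeofactor:Landfills", "edgecov:distance_km"])
        y = vergm.simulate_network(np.array([1.5, 0.8, -0.1]), model, seed=11)
        fit = vergm.fit_mle(y, model)
        yv = y[model.pair_i, model.pair_j]
        ref = sm.GLM(yv, model.X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.theta, ref.params, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-3)

    def test_collinear_model_rejected_at_fit(self):
        # out-factors for every habitat of a 2-habitat network + sum: collinear
        D = np.zeros((4, 4))
        model = vergm.ErgmModel(
            ["sum", "nodeofactor:Landfills", "nodeofactor:Marshes"],
            ["Landfills", "Marshes", "Landfills", "Marshes"],
            {"distance_km": D},
        )
        with pytest.raises(ValueError, match="identifiable"):
            vergm.fit_mle(np.zeros((4, 4), dtype=int), model)

    def test_fit_report_shape(self):
        model = small_model(seed=13)
        y = vergm.simulate_network(np.array([1.2, 0.4, -0.3, -0.05, 0.3]), model, seed=5)
        fit = vergm.fit_mle(y, model)
        df = fit.summary()
        assert list(df.columns) == ["term", "estimate", "se", "z", "p"]
        np.testing.assert_allclose(np.abs(df["z"]), np.abs(df["estimate"]) / df["se"])
        assert ((df["p"] >= 0) & (df["p"] <= 1)).all()


class TestSimulation:
    def test_poisson_limit_mean(self):
        # theta_sum = log 2, no mutuality: counts iid Poisson(2)
        habs = ["Landfills"] * 34
        model = vergm.ErgmModel(["sum"], habs)
        y = vergm.simulate_network(np.array([math.log(2.0)]), model, seed=0)
        counts = y[~np.eye(34, dtype=bool)]
        assert len(counts) == 1122
        assert counts.mean() == pytest.approx(2.0, abs=0.15)

    def test_mutuality_reduces_asymmetry(self):
        habs = ["Landfills"] * 20
        model = vergm.ErgmModel(["sum", "mutuality"], habs)
        y0 = vergm.simulate_network(np.array([1.5, 0.0]), model, seed=3)
        y1 = vergm.simulate_network(np.array([1.5, 1.0]), model, seed=3)
        asym = lambda y: np.abs(y - y.T)[np.triu_indices(20, 1)].mean()
        assert asym(y1) < asym(y0)

    def test_same_seed_identical(self):
        model = small_model(seed=17)
        theta = np.array([1.0, 0.3, -0.2, -0.1, 0.5])
        np.testing.assert_array_equal(
            vergm.simulate_network(theta, model, seed=9), vergm.simulate_network(theta, model, seed=9)
        )

    def test_poisson_gof_with_zero_mutuality(self):
        # chi-square goodness of fit of per-pair counts against Poisson(e^eta)
        n = 46  # 2070 ordered pairs
        habs = ["Landfills"] * n
        model = vergm.ErgmModel(["sum", "mutuality"], habs)
        lam = 2.0
        y = vergm.simulate_network(np.array([math.log(lam), 0.0]), model, seed=21)
        counts = y[~np.eye(n, dtype=bool)]
        kmax = 8
        obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        pk = stats.poisson.pmf(np.arange(kmax), lam)
        probs = np.append(pk, 1 - pk.sum())
        chi2, p = stats.chisquare(obs, probs * len(counts))
        assert p > 0.01

    def test_simulated_stats_match_model_expectations(self):
        # law of large numbers: mean sufficient statistics over replicates
        # approach E_theta[g] from the truncated pmfs, within 3 MC SEs
        model = small_model(seed=23)
        theta = np.array([1.0, 0.5, -0.4, -0.08, 0.6])
        g_obs = np.array(
            [model.sufficient_stats(vergm.simulate_network(theta, model, seed=s)) for s in range(1000, 1200)]
        )
        eta = model.linear_predictor(theta)
        _, m = vergm.dyad_moments(eta[model.row_ij], eta[model.row_ji], theta[-1])
        Ew = np.empty(len(eta))
        Ew[model.row_ij] = m["Ea"]
        Ew[model.row_ji] = m["Eb"]
        expected = model.join_parts(model.X.T @ Ew, -m["Eabs"].sum())
        mc_se = g_obs.std(axis=0, ddof=1) / math.sqrt(len(g_obs))
        assert np.all(np.abs(g_obs.mean(axis=0) - expected) <= 3 * mc_se + 1e-9)


class TestCoefficientMultiplier:
    def test_identity_at_zero(self):
        assert vergm.coefficient_multiplier(0.0)[0] == 1.0

    def test_full_precision_values(self):
        val, text = vergm.coefficient_multiplier(4.75)
        assert val == pytest.approx(math.exp(4.75), rel=1e-15)
        assert "116" in text or "115" in text
        assert vergm.coefficient_multiplier(1.49)[0] == pytest.approx(4.4371, abs=1e-4)
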