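"""ABC machinery: priors, rejection, GLM model choice, posteriors, PLS."""

import numpy as np
import pytest
from scipy import stats as sps

from invasionabc.abcfit import (
    ABCError,
    ParameterPosterior,
    PriorSpec,
    ReferenceTable,
    model_posterior,
    parameter_posterior,
    pls_project,
    retain_nearest,
    robust_scale,
    to_sim_params,
    weight_posteriors,
)


class TestPrior:
    def test_tau_ordering_always_satisfied(self, rng):
        prior = PriorSpec()
        for _ in range(2000):
            d = prior.sample(rng)
            assert d["tau_HI"] > d["tau_WUS"] > d["tau_SP"] > d["tau_EUS"]
            assert d["mu"] > 0

    def test_nm_marginal_uniform(self, rng):
        prior = PriorSpec()
        draws = np.array([prior.sample(rng)["log10_Nm"] for _ in range(3000)])
        assert sps.kstest(draws, sps.uniform(loc=-2, scale=4).cdf).pvalue > 0.01

    def test_tau_ordering_acceptance_rate_one_sixth(self, rng):
        """The rejection step accepts orderings of three iid uniforms:
        exactly one of the 3! orders, so 1/6 of raw draws."""
        hits = 0
        n = 30000
        u = rng.uniform(10, 100, size=(n, 3))
        hits = (u[:, 0] > u[:, 2]) & (u[:, 2] > u[:, 1])  # WUS > SP > EUS
        assert hits.mean() == pytest.approx(1 / 6, abs=0.01)

    def test_to_sim_params_scales(self):
        d = {"log10_N_JP": 3.0, "tau_EUS": 20.0, "mu": 1e-9}
        p = to_sim_params(d)
        assert p == {"N_JP": 1000.0, "tau_EUS": 20.0, "mu": 1e-9}


class TestRetention:
    def _table(self, rng, n=50, d=3):
        return rng.normal(size=(n, d))

    def test_exact_row_has_distance_zero(self, rng):
        stats = self._table(rng)
        ret = retain_nearest(stats, stats[7], k=5)
        assert ret.indices[0] == 7
        assert ret.distances[0] == 0.0

    def test_k_equals_table_size_keeps_all(self, rng):
        stats = self._table(rng)
        ret = retain_nearest(stats, stats.mean(axis=0), k=50)
        assert sorted(ret.indices) == list(range(50))
        assert np.all(np.diff(ret.distances) >= 0)

    def test_five_row_toy_matches_brute_force_sort(self):
        stats = np.array([[0.0], [1.0], [2.0], [3.0], [4.0]])
        obs = np.array([2.2])
        center, scale = robust_scale(stats)
        z = (stats - center) / scale
        zo = (obs - center) / scale
        brute = np.argsort(np.abs(z[:, 0] - zo[0]), kind="stable")
        ret = retain_nearest(stats, obs, k=5)
        assert list(ret.indices) == list(brute)

    def test_k_too_large_raises(self, rng):
        with pytest.raises(ABCError):
            retain_nearest(self._table(rng), np.zeros(3), k=51)


def _gaussian_tables(rng, n, means, sd=1.0, informative=False):
    tables = {}
    for name, mu in means.items():
        theta = rng.uniform(-1, 1, (n, 1))
        loc = mu + (theta if informative else 0)
        stats = rng.normal(loc, sd, (n, 1))
        tables[name] = ReferenceTable(name, theta, stats, ["t"], ["s"])
    return tables


class TestModelChoice:
    def test_separated_clouds(self, rng):
        tables = _gaussian_tables(rng, 3000, {"A": 0.0, "B": 40.0, "C": -40.0})
        post = model_posterior(tables, np.array([0.1]), ["s"], k=500)
        assert post.probabilities["A"] > 0.99
        assert post.best == "A"

    def test_identical_distributions_near_uniform(self, rng):
        tables = _gaussian_tables(rng, 4000, {"A": 0.0, "B": 0.0, "C": 0.0})
        post = model_posterior(tables, np.array([0.2]), ["s"], k=800)
        for p in post.probabilities.values():
            assert p == pytest.approx(1 / 3, abs=0.08)

    def test_matches_analytic_bayes_factor_within_two_percent(self):
        """1-D Gaussian clouds: GLM posterior vs the closed-form Bayes
        factor, averaged over replicate tables."""
        rng = np.random.default_rng(123)
        errs = []
        for _ in range(12):
            tables = _gaussian_tables(rng, 5000, {"A": 0.0, "B": 3.0})
            post = model_posterior(tables, np.array([1.0]), ["s"], k=1200)
            la, lb = sps.norm.pdf(1.0, 0.0, 1.0), sps.norm.pdf(1.0, 3.0, 1.0)
            errs.append(post.probabilities["A"] - la / (la + lb))
        assert abs(np.mean(errs)) < 0.02

    def test_invariant_to_statistic_rescaling(self, rng):
        tables = _gaussian_tables(rng, 2000, {"A": 0.0, "B": 2.0})
        obs = np.array([0.5])
        p1 = model_posterior(tables, obs, ["s"], k=400).probabilities
        scaled = {
            m: ReferenceTable(m, t.params, t.stats * 1000.0, t.param_names, t.stat_names)
            for m, t in tables.items()
        }
        p2 = model_posterior(scaled, obs * 1000.0, ["s"], k=400).probabilities
        for m in p1:
            assert p1[m] == pytest.approx(p2[m], abs=1e-9)

    def test_probabilities_sum_to_one(self, rng):
        tables = _gaussian_tables(rng, 1000, {"A": 0.0, "B": 1.0, "C": 2.0})
        post = model_posterior(tables, np.array([1.2]), ["s"], k=300)
        assert sum(post.probabilities.values()) == pytest.approx(1.0)

    def test_logistic_fallback_agrees_qualitatively(self, rng):
        tables = _gaussian_tables(rng, 2000, {"A": 0.0, "B": 6.0})
        post = model_posterior(tables, np.array([0.0]), ["s"], k=400, method="logistic")
        assert post.best == "A"

    def test_non_finite_observed_raises(self, rng):
        tables = _gaussian_tables(rng, 100, {"A": 0.0, "B": 1.0})
        with pytest.raises(ABCError):
            model_posterior(tables, np.array([np.nan]), ["s"], k=50)


class TestPLS:
    def test_planted_linear_signal_recovered(self, rng):
        """Two statistics carry the parameters linearly; PLS components
        should span that subspace (small principal angle)."""
        n, p_noise = 3000, 8
        theta = rng.normal(size=(n, 2))
        signal = theta @ np.array([[1.0, 0.3], [-0.5, 1.0]])
        noise = rng.normal(size=(n, p_noise))
        stats = np.column_stack([signal + 0.05 * rng.normal(size=(n, 2)), noise])
        scores, proj = pls_project(stats, theta, n_components=2)
        W = proj.pls.x_rotations_  # columns: component directions in stat space
        # signal subspace = first two coordinates
        signal_basis = np.zeros((stats.shape[1], 2))
        signal_basis[0, 0] = signal_basis[1, 1] = 1.0
        # principal angle between the two subspaces
        q1, _ = np.linalg.qr(W)
        q2, _ = np.linalg.qr(signal_basis)
        sv = np.linalg.svd(q1.T @ q2, compute_uv=False)
        angle_deg = np.degrees(np.arccos(np.clip(sv.min(), -1, 1)))
        assert angle_deg < 5.0

    def test_full_components_invertible(self, rng):
        n, d = 500, 4
        theta = rng.normal(size=(n, 2))
        stats = rng.normal(size=(n, d)) + np.column_stack([theta, theta])
        scores, proj = pls_project(stats, theta, n_components=d)
        # the rotation matrix is invertible: standardized stats are
        # recoverable from the scores
        W = proj.pls.x_rotations_
        assert np.linalg.matrix_rank(W) == d
        # reconstruction through the (invertible) rotation recovers the
        # internally centered/scaled statistics
        z = (stats - proj.center) / proj.scale
        z_internal = (z - proj.pls._x_mean) / proj.pls._x_std
        assert np.allclose(scores @ np.linalg.pinv(W), z_internal, atol=1e-8)

    def test_permuted_parameters_capture_no_covariance(self, rng):
        n = 2000
        theta = rng.normal(size=(n, 2))
        stats = np.column_stack([theta + 0.01 * rng.normal(size=(n, 2)), rng.normal(size=(n, 4))])
        theta_perm = rng.permutation(theta)
        _, proj_signal = pls_project(stats, theta, n_components=2)
        _, proj_null = pls_project(stats, theta_perm, n_components=2)

        def r_squared(proj, target):
            scores = proj.transform(stats)
            X = np.column_stack([np.ones(n), scores])
            beta, *_ = np.linalg.lstsq(X, target[:, 0], rcond=None)
            resid = target[:, 0] - X @ beta
            return 1 - resid.var() / target[:, 0].var()

        # components trained on the true parameters explain them; trained
        # on permuted parameters they explain (essentially) nothing about
        # their own training target
        assert r_squared(proj_signal, theta) > 0.95
        assert r_squared(proj_null, theta_perm) < 0.05

    def test_rank_deficiency_raises(self, rng):
        stats = np.tile(rng.normal(size=(100, 1)), (1, 5))
        with pytest.raises(ABCError):
            pls_project(stats, rng.normal(size=(100, 2)), n_components=3)


class _UniPrior:
    names = ["theta"]

    def support(self, name):
        return (-5.0, 5.0)


class TestParameterPosterior:
    def _retained(self, rng, informative=True, n=12000, k=1500, sd=1.0):
        theta = rng.uniform(-5, 5, (n, 1))
        stats = (theta if informative else 0.0) + sd * rng.normal(size=(n, 1))
        obs = np.array([0.7])
        ret = retain_nearest(stats, obs, k)
        z = (stats[ret.indices] - ret.center) / ret.scale
        zo = (obs - ret.center) / ret.scale
        return parameter_posterior(theta[ret.indices], z, zo, _UniPrior())

    def test_uninformative_stats_return_prior(self, rng):
        post = self._retained(rng, informative=False)
        g = post.grids["theta"]
        dens = post.densities["theta"]
        flat = np.full_like(dens, 1 / (g[-1] - g[0]))
        tv = 0.5 * np.trapezoid(np.abs(dens - flat), g)
        assert tv < 0.1

    def test_noiseless_linear_stat_concentrates(self, rng):
        post = self._retained(rng, informative=True, sd=1e-4)
        s = post.summary("theta")
        assert s["median"] == pytest.approx(0.7, abs=0.05)
        assert s["q95"] - s["q5"] < 0.2

    def test_conjugate_gaussian_quantiles(self, rng):
        """theta ~ U[-5,5], s|theta ~ N(theta, 1), s_obs = 0.7: posterior
        is N(0.7, 1) truncated; quantiles match the closed form."""
        post = self._retained(rng, informative=True, sd=1.0)
        s = post.summary("theta")
        assert s["mean"] == pytest.approx(0.7, abs=0.1)
        assert s["q5"] == pytest.approx(0.7 - 1.645, abs=0.15)
        assert s["q95"] == pytest.approx(0.7 + 1.645, abs=0.15)
        # CDF value of the truth
        assert post.quantile_of("theta", 0.7) == pytest.approx(0.5, abs=0.05)

    def test_degenerate_retained_raises(self, rng):
        with pytest.raises(ABCError):
            parameter_posterior(np.zeros((3, 1)), np.zeros((3, 1)), np.zeros(1), _UniPrior())


class TestWeightPosteriors:
    def _point_posterior(self, at, width=0.05):
        g = np.linspace(-5, 5, 512)
        d = np.exp(-0.5 * ((g - at) / width) ** 2)
        d /= np.trapezoid(d, g)
        return ParameterPosterior(["theta"], {"theta": g}, {"theta": d})

    def test_degenerate_weights_return_component(self):
        a, b = self._point_posterior(-1.0), self._point_posterior(2.0)
        w = weight_posteriors({"A": a, "B": b}, {"A": 1.0, "B": 0.0})
        assert np.allclose(w.densities["theta"], a.densities["theta"])

    def test_identical_components_unchanged(self):
        a = self._point_posterior(0.5)
        w = weight_posteriors({"A": a, "B": self._point_posterior(0.5)}, {"A": 0.4, "B": 0.6})
        assert np.allclose(w.densities["theta"], a.densities["theta"], atol=1e-12)

    def test_mixture_mean_is_weighted_average(self):
        a, b = self._point_posterior(-1.0), self._point_posterior(2.0)
        w = weight_posteriors({"A": a, "B": b}, {"A": 0.3, "B": 0.7})
        assert w.mean("theta") == pytest.approx(0.3 * -1.0 + 0.7 * 2.0, abs=0.02)

    def test_missing_parameter_raises(self):
        a = self._point_posterior(0.0)
        b = ParameterPosterior(["other"], {"other": a.grids["theta"]}, {"other": a.densities["theta"]})
        with pytest.raises(ABCError):
            weight_posteriors({"A": a, "B": b}, {"A": 0.5, "B": 0.5})
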