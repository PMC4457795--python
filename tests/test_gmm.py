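import numpy as np
import pytest
from scipy.stats import norm

from retivote.gmm import (
    GMMFit,
    IntensityGMM,
    assign_clusters,
    em_fit,
    kmeans_init,
    select_vessel_cluster,
)


class TestKMeansInit:
    def test_two_point_masses(self):
        values = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        means, variances, weights = kmeans_init(values, 2, seed=0)
        assert np.allclose(sorted(means), [0.0, 1.0])
        assert np.allclose(weights, [0.5, 0.5])
        assert np.all(variances >= 1e-6)

    def test_k1_gives_sample_moments(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0.4, 0.1, 500)
        means, variances, weights = kmeans_init(values, 1, seed=0)
        assert means[0] == pytest.approx(values.mean())
        assert variances[0] == pytest.approx(values.var(), rel=1e-9)
        assert weights[0] == 1.0

    def test_mixture_centers_recovered(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.normal(0.2, 0.05, 5000),
                                 rng.normal(0.8, 0.05, 5000)])
        means, _, _ = kmeans_init(values, 2, seed=0)
        assert abs(sorted(means)[0] - 0.2) < 0.02
        assert abs(sorted(means)[1] - 0.8) < 0.02

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            kmeans_init(np.array([1.0, 1.0, 1.0]), 2)


class TestEMFit:
    def test_k1_equals_sample_moments_after_one_iteration(self):
        rng = np.random.default_rng(2)
        values = rng.normal(0.5, 0.2, 1000)
        init = (np.array([0.0]), np.array([1.0]), np.array([1.0]))
        fit = em_fit(values, init, max_iter=1)
        assert fit.means[0] == pytest.approx(values.mean())
        assert fit.variances[0] == pytest.approx(values.var(), rel=1e-9)
        assert fit.weights[0] == pytest.approx(1.0)

    def test_loglik_monotone_and_weights_normalized(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            values = rng.random(400)
            init = kmeans_init(values, 3, seed=0)
            fit = em_fit(values, init, max_iter=50)
            diffs = np.diff(fit.loglik_trace)
            assert np.all(diffs >= -1e-9)
            assert np.allclose(fit.weights_trace.sum(axis=1), 1.0, atol=1e-12)

    def test_responsibilities_match_bruteforce_posterior(self):
        # one E-step with frozen parameters equals the per-point posterior
        # computed directly from the normal density
        rng = np.random.default_rng(4)
        values = rng.random(50)
        w = np.array([0.3, 0.7])
        mu = np.array([0.25, 0.75])
        var = np.array([0.01, 0.04])
        fit = em_fit(values, (mu, var, w), max_iter=1)
        # after one M-step the weights are the mean posterior; recompute that
        post = np.empty((50, 2))
        for j, x in enumerate(values):
            dens = w * norm.pdf(x, mu, np.sqrt(var))
            post[j] = dens / dens.sum()
        assert np.allclose(fit.weights, post.mean(axis=0), atol=1e-12)
        assert np.allclose(
            fit.means, (post * values[:, None]).sum(0) / post.sum(0), atol=1e-12
        )

    def test_two_component_parameter_recovery(self):
        rng = np.random.default_rng(5)
        n = 50_000
        comp = rng.random(n) < 0.7
        values = np.where(comp, rng.normal(0.3, 0.05, n), rng.normal(0.7, 0.05, n))
        fit = em_fit(values, kmeans_init(values, 2, seed=0))
        order = np.argsort(fit.means)
        assert abs(fit.means[order[0]] - 0.3) / 0.3 < 0.05
        assert abs(fit.means[order[1]] - 0.7) / 0.7 < 0.05
        assert abs(fit.weights[order[0]] - 0.7) / 0.7 < 0.05
        assert abs(np.sqrt(fit.variances[order[0]]) - 0.05) / 0.05 < 0.05

    def test_variance_floor_applied_with_warning(self):
        values = np.concatenate([np.full(50, 0.2), np.full(50, 0.8)]) \
            + np.linspace(0, 1e-9, 100)
        init = (np.array([0.2, 0.8]), np.array([1e-4, 1e-4]), np.array([0.5, 0.5]))
        with pytest.warns(UserWarning, match="collapsed"):
            fit = em_fit(values, init, max_iter=20)
        assert np.all(fit.variances >= 1e-6)


class TestAssign:
    def _fit(self, w, mu, var):
        return GMMFit(np.asarray(w, float), np.asarray(mu, float),
                      np.asarray(var, float), np.zeros(1), np.ones((1, len(w))),
                      1, 0)

    def test_point_at_mean_of_tight_component(self):
        fit = self._fit([0.5, 0.5], [0.2, 0.8], [0.01, 0.04])
        assert assign_clusters(fit, np.array([0.2]))[0] == 0

    def test_partition_property(self):
        rng = np.random.default_rng(6)
        values = rng.random(200)
        fit = self._fit([0.3, 0.7], [0.3, 0.7], [0.02, 0.02])
        labels = assign_clusters(fit, values)
        layers = [labels == i for i in range(2)]
        assert np.array_equal(layers[0] | layers[1], np.ones(200, bool))
        assert not (layers[0] & layers[1]).any()

    def test_equal_variance_boundary_at_weighted_midpoint(self):
        # argmax_i w_i N(x; mu_i, s^2) flips at
        # x* = (mu1+mu2)/2 + s^2 ln(w1/w2) / (mu2-mu1)
        w1, w2, mu1, mu2, s2 = 0.8, 0.2, 0.3, 0.7, 0.01
        boundary = (mu1 + mu2) / 2 + s2 * np.log(w1 / w2) / (mu2 - mu1)
        fit = self._fit([w1, w2], [mu1, mu2], [s2, s2])
        eps = 1e-6
        labels = assign_clusters(fit, np.array([boundary - eps, boundary + eps]))
        assert labels[0] == 0 and labels[1] == 1
        # unweighted assignment flips at the plain midpoint instead
        labels_u = assign_clusters(
            fit, np.array([0.5 - eps, 0.5 + eps]), weighted=False
        )
        assert labels_u[0] == 0 and labels_u[1] == 1


class TestSelectVesselCluster:
    def _fit(self, w, mu):
        w = np.asarray(w, float)
        mu = np.asarray(mu, float)
        return GMMFit(w, mu, np.full(w.size, 0.01), np.zeros(1),
                      np.ones((1, w.size)), 1, 0)

    def test_index_rule_is_passthrough(self):
        fit = self._fit([0.25] * 4, [0.1, 0.2, 0.3, 0.4])
        labels = np.array([0, 1, 2, 3, 3])
        mask, comp = select_vessel_cluster(fit, labels, rule="index:3")
        assert comp == 3
        assert np.array_equal(mask, labels == 3)

    def test_brightest_major_skips_tail_cluster(self):
        # a 0.5%-weight extreme-value tail outranks the vessel layer by
        # mean; the default rule must skip it
        fit = self._fit([0.60, 0.25, 0.145, 0.005], [0.02, 0.05, 0.30, 0.55])
        labels = np.array([0, 1, 2, 3])
        _, comp = select_vessel_cluster(fit, labels, rule="brightest_major")
        assert comp == 2
        _, comp_h = select_vessel_cluster(fit, labels, rule="highest")
        assert comp_h == 3
        _, comp_2 = select_vessel_cluster(fit, labels, rule="second_highest")
        assert comp_2 == 2

    def test_single_component_rejected(self):
        fit = self._fit([1.0], [0.5])
        with pytest.raises(ValueError, match="at least 2"):
            select_vessel_cluster(fit, np.zeros(3, int))


class TestIntensityGMMEstimator:
    def test_fit_is_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        values = rng.random(2000)
        a = IntensityGMM(n_components=3, random_state=0).fit(values)
        b = IntensityGMM(n_components=3, random_state=0).fit(values)
        assert np.array_equal(a.means_, b.means_)
        assert np.array_equal(a.weights_, b.weights_)
        assert np.array_equal(a.loglik_trace_, b.loglik_trace_)

    def test_sklearn_protocol(self):
        model = IntensityGMM(n_components=2)
        params = model.get_params()
        assert params["n_components"] == 2
        model.set_params(n_components=3)
        assert model.n_components == 3

    def test_agrees_with_sklearn_mixture_on_separated_data(self):
        # independent cross-check of the whole fit on easy data
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(8)
        values = np.concatenate([rng.normal(0.2, 0.04, 4000),
                                 rng.normal(0.75, 0.06, 2000)])
        ours = IntensityGMM(n_components=2, random_state=0).fit(values)
        ref = GaussianMixture(2, random_state=0).fit(values[:, None])
        assert np.allclose(sorted(ours.means_), sorted(ref.means_.ravel()),
                           atol=0.01)
        assert np.allclose(sorted(ours.weights_), sorted(ref.weights_),
                           atol=0.01)

    def test_rejects_bad_input(self):
        model = IntensityGMM()
        with pytest.raises(ValueError):
            model.fit(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            model.fit(np.array([0.1, np.nan, 0.3]))
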