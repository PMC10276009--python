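"""The Pareto-mixture likelihood, its normalisation, and the Gibbs sampler."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import comb

from idmix._gibbs import _label_sweep, _label_sweep_py
from idmix.hidalgo import (
    HidalgoConfig,
    _in_csr,
    augmented_loglik,
    gibbs_fit,
    log_partition_table,
    mixture_density,
)
from idmix.twonn import neighbourhood_matrix, nn_distances, nn_indices, ratios


class TestMixtureDensity:
    def test_single_component_value(self):
        # L=1, d=1: f(e) = 1 * e^{-2}
        assert mixture_density(np.e, [1.0], [1.0]) == pytest.approx(np.exp(-2))

    def test_degenerate_mixture_equals_single(self):
        mu = 1.7
        one = mixture_density(mu, [1.0], [1.0])
        two = mixture_density(mu, [1.0, 1.0], [0.5, 0.5])
        assert one == pytest.approx(two)

    def test_domain_error(self):
        with pytest.raises(ValueError, match="mu"):
            mixture_density(0.5, [2.0], [1.0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_integrates_to_one(self, seed):
        rng = np.random.default_rng(seed)
        L = rng.integers(1, 5)
        d = rng.uniform(0.5, 12.0, size=L)
        pi = rng.dirichlet(np.ones(L))
        total, err = quad(lambda m: mixture_density(m, d, pi), 1, np.inf)
        assert total == pytest.approx(1.0, abs=max(1e-8, 10 * err))


class TestPartitionTable:
    def test_against_direct_combinatorics(self):
        n, q, zeta = 12, 3, 0.8
        logZ = log_partition_table(n, q, zeta)
        for s in range(1, n + 1):
            direct = sum(
                comb(s - 1, k) * comb(n - s, q - k) * zeta**k * (1 - zeta) ** (q - k)
                for k in range(q + 1)
            )
            assert logZ[s] == pytest.approx(np.log(direct))

    def test_constant_at_half(self):
        # zeta = 0.5: Z(s) = 0.5^q C(n-1, q) independently of the cluster size
        logZ = log_partition_table(20, 4, 0.5)
        expected = 4 * np.log(0.5) + np.log(comb(19, 4))
        assert np.allclose(logZ[1:], expected)


class TestAugmentedLoglik:
    @staticmethod
    def _toy():
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(20, 1, (3, 2))])
        mu = ratios(nn_distances(X, 2))
        N = neighbourhood_matrix(X, 2)
        return mu, N

    def test_zeta_half_reduces_to_pareto(self):
        mu, N = self._toy()
        d = np.array([1.5, 6.0])
        configs = [np.array(c) for c in ([0, 0, 0, 1, 1, 1], [0, 1, 0, 1, 0, 1], [1, 1, 1, 0, 0, 0])]
        for ca, cb in zip(configs, configs[1:]):
            delta_full = augmented_loglik(mu, N, ca, d, 0.5) - augmented_loglik(mu, N, cb, d, 0.5)
            pareto = lambda c: np.sum(np.log(d[c]) - (d[c] + 1) * np.log(mu))
            assert delta_full == pytest.approx(pareto(ca) - pareto(cb))

    def test_single_cluster_counting(self):
        # all points share the cluster: every row contributes (q, 0) exponents
        mu, N = self._toy()
        c = np.zeros(6, dtype=int)
        d = np.array([2.0])
        q, zeta, n = 2, 0.75, 6
        logZ = log_partition_table(n, q, zeta)
        expected = (
            np.sum(np.log(2.0) - 3.0 * np.log(mu))
            + n * q * np.log(zeta)
            - n * logZ[n]
        )
        assert augmented_loglik(mu, N, c, d, zeta) == pytest.approx(expected)

    def test_hand_expanded_two_cluster_toy(self):
        # independent term-by-term evaluation with explicit python loops
        mu, N = self._toy()
        c = np.array([0, 0, 0, 1, 1, 1])
        d = np.array([1.5, 6.0])
        zeta, q, n = 0.75, 2, 6
        logZ = log_partition_table(n, q, zeta)
        sizes = [3, 3]
        expected = 0.0
        for i in range(n):
            expected += np.log(d[c[i]]) - (d[c[i]] + 1) * np.log(mu[i])
            same = sum(N[i, j] for j in range(n) if c[j] == c[i])
            expected += same * np.log(zeta) + (q - same) * np.log(1 - zeta)
            expected -= logZ[sizes[c[i]]]
        assert augmented_loglik(mu, N, c, d, zeta) == pytest.approx(expected)


def _random_geometry(n, q, seed):
    X = np.random.default_rng(seed).normal(size=(n, 3))
    mu = ratios(nn_distances(X, 2))
    nbr = nn_indices(X, q)
    return mu, nbr


class TestGibbs:
    def test_determinism(self):
        mu, nbr = _random_geometry(40, 3, 0)
        cfg = HidalgoConfig(L=4, n_iter=300, burn_in=50, seed=11)
        a = gibbs_fit(mu, nbr, cfg)
        b = gibbs_fit(mu, nbr, cfg)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.dims, b.dims)
        assert np.array_equal(a.weights, b.weights)

    def test_weights_are_simplex(self):
        mu, nbr = _random_geometry(30, 3, 1)
        chains = gibbs_fit(mu, nbr, HidalgoConfig(L=5, n_iter=400, burn_in=100, seed=2))
        assert np.allclose(chains.weights.sum(axis=1), 1.0, atol=1e-9)
        assert (chains.dims > 0).all()
        assert chains.n_kept == 300

    def test_conjugate_posterior_single_component(self):
        # with L=1 the d-draws are iid Gamma(a+n, b+sum log mu)
        n = 100
        mu = np.exp(np.full(n, 0.5))  # sum log mu = 50
        nbr = nn_indices(np.random.default_rng(3).normal(size=(n, 3)), 3)
        cfg = HidalgoConfig(L=1, a_d=1.0, b_d=1.0, n_iter=4000, burn_in=500, seed=4)
        chains = gibbs_fit(mu, nbr, cfg)
        closed_form = (1 + n) / (1 + 50.0)
        mc_se = chains.dims.std(ddof=1) / np.sqrt(chains.n_kept)
        assert abs(chains.dims.mean() - closed_form) < 3 * mc_se

    def test_prior_recovery_without_data(self):
        cfg = HidalgoConfig(L=2, a_d=2.0, b_d=0.5, n_iter=6000, burn_in=0, seed=5)
        chains = gibbs_fit(np.array([]), None, cfg)
        draws = chains.dims.ravel()
        se_mean = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 4.0) < 4 * se_mean  # Gamma(2, 0.5) mean
        assert abs(draws.var(ddof=1) - 8.0) < 0.5  # and variance

    def test_sample_zeta_flag_runs(self):
        mu, nbr = _random_geometry(30, 3, 6)
        cfg = HidalgoConfig(L=3, n_iter=200, burn_in=50, seed=7, sample_zeta=True)
        chains = gibbs_fit(mu, nbr, cfg)
        assert chains.zeta_chain is not None
        assert ((chains.zeta_chain > 0.5) & (chains.zeta_chain < 1)).all()

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            HidalgoConfig(burn_in=10, n_iter=10)
        with pytest.raises(ValueError):
            HidalgoConfig(zeta=0.4)


class TestLabelSweepKernel:
    """The compiled sweep must match the model equations and the pure-Python path."""

    @staticmethod
    def _state(n=25, L=3, q=3, seed=0):
        mu, nbr = _random_geometry(n, q, seed)
        rng = np.random.default_rng(seed + 100)
        labels = rng.integers(0, L, n).astype(np.int64)
        d = rng.uniform(0.5, 8, L)
        pi = rng.dirichlet(np.ones(L))
        return mu, nbr, labels, d, pi

    def test_numba_matches_python(self):
        mu, nbr, labels, d, pi = self._state()
        n, L, q = labels.size, d.size, nbr.shape[1]
        logZ = log_partition_table(n, q, 0.75)
        in_ptr, in_idx = _in_csr(nbr, n)
        rng = np.random.default_rng(1)
        order = rng.permutation(n).astype(np.int64)
        gumbels = rng.gumbel(size=(n, L))
        args = (np.log(mu), nbr, in_ptr, in_idx, np.log(pi), np.log(d), d,
                logZ, np.log(0.75), np.log(0.25))
        lab_a, sz_a = labels.copy(), np.bincount(labels, minlength=L).astype(np.int64)
        lab_b, sz_b = labels.copy(), sz_a.copy()
        _label_sweep(order, gumbels, lab_a, sz_a, *args)
        _label_sweep_py(order, gumbels, lab_b, sz_b, *args)
        assert np.array_equal(lab_a, lab_b)
        assert np.array_equal(sz_a, sz_b)

    def test_greedy_choice_matches_full_conditional(self):
        # with zero Gumbel noise the sweep picks argmax_l of
        # log pi_l + augmented log-likelihood with c_i = l
        mu, nbr, labels, d, pi = self._state(n=15, L=3, q=2, seed=2)
        n, L, q = labels.size, d.size, nbr.shape[1]
        N = np.zeros((n, n), dtype=np.int8)
        N[np.repeat(np.arange(n), q), nbr.ravel()] = 1
        zeta = 0.8
        logZ = log_partition_table(n, q, zeta)
        in_ptr, in_idx = _in_csr(nbr, n)
        for i in range(n):
            expected_scores = []
            for l in range(L):
                c = labels.copy()
                c[i] = l
                expected_scores.append(np.log(pi[l]) + augmented_loglik(mu, N, c, d, zeta))
            expected = int(np.argmax(expected_scores))
            lab = labels.copy()
            sz = np.bincount(lab, minlength=L).astype(np.int64)
            _label_sweep_py(
                np.array([i], dtype=np.int64), np.zeros((1, L)), lab, sz,
                np.log(mu), nbr, in_ptr, in_idx, np.log(pi), np.log(d), d,
                logZ, np.log(zeta), np.log(1 - zeta),
            )
            assert lab[i] == expected

    def test_zeta_half_conditionals_reduce_to_plain_mixture(self):
        # neighbourhood factors cancel: choice = argmax of Pareto-mixture terms
        mu, nbr, labels, d, pi = self._state(n=20, L=4, q=3, seed=3)
        n, L, q = labels.size, d.size, nbr.shape[1]
        logZ = log_partition_table(n, q, 0.5)
        in_ptr, in_idx = _in_csr(nbr, n)
        rng = np.random.default_rng(4)
        for i in range(n):
            g = rng.gumbel(size=(1, L))
            plain = np.log(pi) + np.log(d) - (d + 1) * np.log(mu[i]) + g[0]
            lab = labels.copy()
            sz = np.bincount(lab, minlength=L).astype(np.int64)
            _label_sweep_py(
                np.array([i], dtype=np.int64), g, lab, sz,
                np.log(mu), nbr, in_ptr, in_idx, np.log(pi), np.log(d), d,
                logZ, np.log(0.5), np.log(0.5),
            )
            assert lab[i] == int(np.argmax(plain))


class TestSparseRecovery:
    def test_two_manifolds_recovered(self, two_manifold_fit):
        from sklearn.metrics import adjusted_rand_score

        model, labels, dims = two_manifold_fit
        assert model.n_clusters_ == 2
        assert adjusted_rand_score(labels, model.labels_) >= 0.8
        est = np.sort(model.cluster_mean_ids_)
        assert np.all(np.abs(est - np.sort(dims)) <= 1.0)

    def test_populated_components_concentrate(self, two_manifold_fit):
        model, _, _ = two_manifold_fit
        populated = np.array([np.unique(row).size for row in model.chains_.labels])
        assert (populated <= model.chains_.config.L).all()
        assert np.mean(populated == 2) > 0.5
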