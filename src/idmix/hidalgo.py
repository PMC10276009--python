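"""Heterogeneous intrinsic-dimension estimation via a Bayesian Pareto mixture.

The model (Hidalgo) assumes the TWO-NN ratios mu_i arise from a finite
mixture of L Pareto(1, d_l) densities,

    f(mu_i | d, pi) = sum_l pi_l d_l mu_i^{-(d_l + 1)},

with conjugate Gamma(a_d, b_d) priors on each d_l and a symmetric
Dirichlet(alpha) prior on the weights. Small concentrations (alpha <= 0.05)
give a sparse mixture: L is only an upper bound and the number of populated
components L* is estimated from the data. Because Pareto supports overlap
completely, the likelihood is augmented with a local-homogeneity term built
on the binary q-neighbourhood matrix N^(q): an observed neighbour link
(i, j) has probability zeta if c_i = c_j and 1 - zeta otherwise, normalised
by the exact combinatorial constant Z_i over q-subsets given cluster sizes.

Inference is a Gibbs sampler: d_l and pi are conjugate block updates, labels
are swept one observation at a time in a random order using Gumbel-max
categorical sampling in log space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import betaln, gammaln
from sklearn.base import BaseEstimator, ClusterMixin

from ._gibbs import _label_sweep
from .postprocess import (
    Partition,
    coclustering,
    observation_chains,
    summarize,
    vi_partition,
)
from .twonn import _as_matrix, _nn_order, jitter_duplicates

__all__ = [
    "HidalgoConfig",
    "HidalgoChains",
    "mixture_density",
    "log_partition_table",
    "augmented_loglik",
    "gibbs_fit",
    "Hidalgo",
]


@dataclass
class HidalgoConfig:
    """Sampler settings. ``alpha`` may be a scalar or a length-L vector."""

    L: int = 6
    a_d: float = 1.0
    b_d: float = 0.1
    alpha: float | np.ndarray = 0.05
    q: int = 3
    zeta: float = 0.70
    sample_zeta: bool = False
    n_iter: int = 25_000
    burn_in: int = 1_000
    seed: int = 0

    def __post_init__(self):
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.a_d <= 0 or self.b_d <= 0:
            raise ValueError("Gamma prior parameters must be positive")
        alpha = np.broadcast_to(np.asarray(self.alpha, dtype=float), (self.L,)).copy()
        if (alpha <= 0).any():
            raise ValueError("Dirichlet concentrations must be positive")
        self.alpha_vec = alpha
        if not (0.5 < self.zeta < 1.0):
            raise ValueError("zeta must lie in (0.5, 1)")
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")

    @property
    def sparse(self) -> bool:
        """True when every concentration is small enough to empty components."""
        return bool((self.alpha_vec <= 0.05).all())


@dataclass
class HidalgoChains:
    """Kept MCMC draws: labels (n_kept × n), weights and dims (n_kept × L)."""

    labels: np.ndarray
    weights: np.ndarray
    dims: np.ndarray
    config: HidalgoConfig
    zeta_chain: np.ndarray | None = None

    @property
    def n_kept(self) -> int:
        return self.labels.shape[0]

    def write(self, outdir) -> None:
        """Chains as three CSV matrices plus a JSON sidecar of the config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savetxt(outdir / "labels_chain.csv", self.labels, fmt="%d", delimiter=",")
        np.savetxt(outdir / "weights_chain.csv", self.weights, delimiter=",")
        np.savetxt(outdir / "dims_chain.csv", self.dims, delimiter=",")
        cfg = asdict(self.config)
        cfg["alpha"] = self.config.alpha_vec.tolist()
        cfg.pop("alpha_vec", None)
        (outdir / "config.json").write_text(json.dumps(cfg, indent=2))


def mixture_density(mu, d, pi) -> np.ndarray | float:
    """Pareto-mixture density sum_l pi_l d_l mu^{-(d_l + 1)}."""
    mu_arr = np.atleast_1d(np.asarray(mu, dtype=float))
    d = np.asarray(d, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if d.shape != pi.shape:
        raise ValueError("d and pi must have the same length")
    if (d <= 0).any():
        raise ValueError("dimensions must be positive")
    if (pi < 0).any() or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("pi must be a probability vector")
    if (mu_arr < 1).any():
        raise ValueError("mu must be >= 1 (Pareto scale is 1)")
    dens = (pi * d * mu_arr[:, None] ** (-(d + 1.0))).sum(axis=1)
    return dens if np.ndim(mu) else float(dens[0])


def log_partition_table(n: int, q: int, zeta: float) -> np.ndarray:
    """log Z(s) for cluster sizes s = 0..n (index 0 is a padding zero).

    Z(s) sums zeta^k (1-zeta)^{q-k} over all ways to pick q neighbours out of
    the other n-1 points when k of them come from the point's own cluster of
    size s: Z(s) = sum_k C(s-1, k) C(n-s, q-k) zeta^k (1-zeta)^{q-k}.
    """
    if not (0 < zeta < 1):
        raise ValueError("zeta must lie in (0, 1)")
    if n <= q:
        raise ValueError("need n > q")
    k = np.arange(q + 1)
    s = np.arange(1, n + 1)[:, None]

    def _logcomb(a, b):
        with np.errstate(invalid="ignore"):
            out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
        return np.where((b >= 0) & (b <= a), out, -np.inf)

    logterms = (
        _logcomb(s - 1, k)
        + _logcomb(n - s, q - k)
        + k * np.log(zeta)
        + (q - k) * np.log1p(-zeta)
    )
    tmax = logterms.max(axis=1, keepdims=True)
    logZ = (tmax + np.log(np.exp(logterms - tmax).sum(axis=1, keepdims=True)))[:, 0]
    return np.concatenate(([0.0], logZ))


def _neighbour_arrays(N) -> tuple[np.ndarray, int]:
    """Validate a binary N^(q) matrix and return (n × q) neighbour indices."""
    N = np.asarray(N)
    if N.ndim != 2 or N.shape[0] != N.shape[1]:
        raise ValueError("N must be square")
    if np.diag(N).any():
        raise ValueError("N must have a zero diagonal")
    rowsums = N.sum(axis=1)
    q = int(rowsums[0])
    if not (rowsums == q).all():
        raise ValueError("every row of N must sum to the same q")
    idx = np.argsort(-N, axis=1, kind="stable")[:, :q]
    return idx.astype(np.int64), q


def augmented_loglik(mu, N, c, d, zeta: float) -> float:
    """Log of the neighbourhood-augmented likelihood at a full configuration.

    Sum over i of the Pareto log-density at d_{c_i}, the Bernoulli
    neighbourhood terms for row i of N, and -log Z_i with Z_i evaluated at
    the size of i's cluster.
    """
    mu = np.asarray(mu, dtype=float)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=float)
    idx, q = _neighbour_arrays(N)
    n = mu.size
    if not (0 < zeta < 1):
        raise ValueError("zeta must lie in (0, 1)")
    same = (c[idx] == c[:, None]).sum(axis=1)  # m_i
    logZ = log_partition_table(n, q, zeta)
    sizes = np.bincount(c, minlength=int(c.max()) + 1)
    pareto = np.log(d[c]) - (d[c] + 1.0) * np.log(mu)
    nbr = same * np.log(zeta) + (q - same) * np.log1p(-zeta)
    return float(pareto.sum() + nbr.sum() - logZ[sizes[c]].sum())


def _in_csr(nbr: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """CSR lists of in-neighbours: points j that list i among their q NNs."""
    q = nbr.shape[1]
    src = np.repeat(np.arange(n, dtype=np.int64), q)
    dst = nbr.ravel()
    order = np.argsort(dst, kind="stable")
    in_idx = src[order]
    counts = np.bincount(dst, minlength=n)
    in_ptr = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
    return in_ptr, in_idx


def gibbs_fit(mu, neighbours, config: HidalgoConfig) -> HidalgoChains:
    """Run the Gibbs sampler and return the kept chains.

    Parameters
    ----------
    mu : array of shape (n,)
        TWO-NN ratios, all >= 1. May be empty, in which case the sampler
        draws from the priors (useful for prior-recovery checks).
    neighbours : int array of shape (n, q) or binary (n, n) matrix
        Out-neighbour index lists, or the binary N^(q) matrix.
    """
    mu = np.asarray(mu, dtype=float)
    n = mu.size
    L = config.L
    rng = np.random.default_rng(config.seed)
    n_kept = config.n_iter - config.burn_in

    if n == 0:
        dims = rng.gamma(config.a_d, 1.0 / config.b_d, size=(n_kept, L))
        weights = rng.dirichlet(config.alpha_vec, size=n_kept)
        labels = np.zeros((n_kept, 0), dtype=np.int64)
        return HidalgoChains(labels, weights, dims, config)

    if (mu < 1).any():
        raise ValueError("ratios must be >= 1")
    nbr = np.asarray(neighbours, dtype=np.int64)
    if nbr.ndim != 2:
        raise ValueError("neighbours must be (n, q) indices or a binary (n, n) matrix")
    if (
        nbr.shape == (n, n)
        and np.isin(nbr, (0, 1)).all()
        and not np.diag(nbr).any()
    ):
        nbr, _ = _neighbour_arrays(nbr)
    if nbr.shape[0] != n:
        raise ValueError("neighbours misaligned with mu")
    q = nbr.shape[1]
    if n <= q:
        raise ValueError("need n > q")
    logmu = np.log(mu)
    in_ptr, in_idx = _in_csr(nbr, n)

    zeta = config.zeta
    logZ = log_partition_table(n, q, zeta)
    labels = rng.integers(0, L, size=n).astype(np.int64)
    sizes = np.bincount(labels, minlength=L).astype(np.int64)
    d = rng.gamma(config.a_d, 1.0 / config.b_d, size=L)
    pi = rng.dirichlet(config.alpha_vec)

    keep_labels = np.empty((n_kept, n), dtype=np.int64)
    keep_weights = np.empty((n_kept, L))
    keep_dims = np.empty((n_kept, L))
    keep_zeta = np.empty(n_kept) if config.sample_zeta else None

    for it in range(config.n_iter):
        order = rng.permutation(n).astype(np.int64)
        gumbels = rng.gumbel(size=(n, L))
        # floor weights so a component that underflows to exactly 0 stays
        # astronomically unlikely rather than producing -inf arithmetic
        log_pi = np.log(np.maximum(pi, 1e-300))
        _label_sweep(
            order, gumbels, labels, sizes, logmu, nbr, in_ptr, in_idx,
            log_pi, np.log(d), d, logZ, np.log(zeta), np.log1p(-zeta),
        )
        counts = np.bincount(labels, minlength=L)
        sumlog = np.bincount(labels, weights=logmu, minlength=L)
        d = rng.gamma(config.a_d + counts, 1.0 / (config.b_d + sumlog))
        pi = rng.dirichlet(config.alpha_vec + counts)
        if config.sample_zeta:
            zeta, logZ = _zeta_step(rng, zeta, logZ, labels, nbr, counts, n, q)
        if not (np.isfinite(d).all() and np.isfinite(pi).all()):
            raise RuntimeError(
                f"non-finite sampler state at iteration {it}: d={d}, pi={pi}, "
                f"counts={counts.tolist()}"
            )
        if it >= config.burn_in:
            t = it - config.burn_in
            keep_labels[t] = labels
            keep_weights[t] = pi
            keep_dims[t] = d
            if keep_zeta is not None:
                keep_zeta[t] = zeta
    return HidalgoChains(keep_labels, keep_weights, keep_dims, config, keep_zeta)


def _zeta_step(rng, zeta, logZ, labels, nbr, counts, n, q,
               a_beta: float = 10.0, b_beta: float = 1.0, step: float = 0.02):
    """Random-walk Metropolis update of zeta under a Beta(10, 1) prior
    truncated to (0.5, 1)."""
    same = int((labels[nbr] == labels[:, None]).sum())
    total = labels.size * q

    def logpost(z, table):
        lp = same * np.log(z) + (total - same) * np.log1p(-z)
        lp -= float(np.sum(counts * table[counts]))  # sum_i log Z(size of c_i)
        lp += (a_beta - 1) * np.log(z) + (b_beta - 1) * np.log1p(-z) - betaln(a_beta, b_beta)
        return lp

    prop = zeta + step * rng.standard_normal()
    if not (0.5 < prop < 1.0):
        return zeta, logZ
    table_prop = log_partition_table(n, q, prop)
    if np.log(rng.uniform()) < logpost(prop, table_prop) - logpost(zeta, logZ):
        return prop, table_prop
    return zeta, logZ


class Hidalgo(ClusterMixin, BaseEstimator):
    """Heterogeneous intrinsic-dimension mixture estimator.

    Fitting computes TWO-NN ratios and the q-neighbourhood matrix from the
    rows of X, runs the Gibbs sampler, and post-processes the chains into a
    label-switching-immune clustering and per-observation ID estimates.

    Parameters
    ----------
    L : int, default=6
        Upper bound on the number of mixture components.
    alpha : float, default=0.05
        Dirichlet concentration; values <= 0.05 give sparse behaviour where
        unnecessary components empty out.
    a_d, b_d : float, default=1.0 and 0.1
        Gamma prior shape and rate on each component dimension. The default
        Gamma(1, 0.1) is flat over the 1-30 range where intrinsic dimensions
        live, so posterior means track the per-cluster likelihood rather
        than being shrunk towards small d.
    q : int, default=3
        Neighbourhood order of the local-homogeneity term.
    zeta : float, default=0.70
        Probability that a q-neighbour shares its point's component. Values
        much closer to 1 strengthen the size-dependent normalisation of the
        neighbourhood term to the point where it can split a large
        homogeneous cluster into spatially compact halves; 0.70 balances
        local-homogeneity glue against that tendency.
    sample_zeta : bool, default=False
        Metropolis-sample zeta under a Beta(10, 1) prior instead of fixing it.
    n_iter, burn_in : int
        Total sweeps and discarded initial sweeps.
    jitter : bool, default=False
        Break exact duplicate rows with seeded 1e-9 uniform noise.
    random_state : int, default=0

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        Point-estimate partition (expected-VI minimiser), coded 0..L*-1.
    n_clusters_ : int
        Number of populated clusters L*.
    pcm_ : ndarray of shape (n, n)
        Posterior co-clustering matrix.
    chains_ : HidalgoChains
        Raw kept draws (labels, weights, dims).
    observation_chains_ : ndarray of shape (n_kept, n)
        Per-observation ID draws d_{c_i}.
    id_summary_ : DataFrame
        Per-observation median ID, central 90% interval, cluster and pooled
        cluster-mean ID.
    cluster_mean_ids_ : ndarray of shape (n_clusters_,)
        Posterior mean ID per estimated cluster, pooled over member draws.
    """

    def __init__(
        self,
        L: int = 6,
        alpha: float = 0.05,
        a_d: float = 1.0,
        b_d: float = 0.1,
        q: int = 3,
        zeta: float = 0.70,
        sample_zeta: bool = False,
        n_iter: int = 25_000,
        burn_in: int = 1_000,
        jitter: bool = False,
        random_state: int = 0,
    ):
        self.L = L
        self.alpha = alpha
        self.a_d = a_d
        self.b_d = b_d
        self.q = q
        self.zeta = zeta
        self.sample_zeta = sample_zeta
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.jitter = jitter
        self.random_state = random_state

    def _config(self) -> HidalgoConfig:
        return HidalgoConfig(
            L=self.L, a_d=self.a_d, b_d=self.b_d, alpha=self.alpha, q=self.q,
            zeta=self.zeta, sample_zeta=self.sample_zeta, n_iter=self.n_iter,
            burn_in=self.burn_in, seed=self.random_state,
        )

    def fit(self, X, y=None):
        X = _as_matrix(X)
        if self.jitter:
            X = jitter_duplicates(X, random_state=self.random_state)
        qmax = max(2, self.q)
        dist, idx = _nn_order(X, qmax)
        if (dist[:, 0] <= 0).any():
            raise ValueError("duplicate rows; set jitter=True or deduplicate")
        self.ratios_ = dist[:, 1] / dist[:, 0]
        self.neighbour_indices_ = idx[:, : self.q]
        self.chains_ = gibbs_fit(self.ratios_, self.neighbour_indices_, self._config())
        self.pcm_ = coclustering(self.chains_.labels)
        part = vi_partition(self.pcm_, self.chains_.labels, exhaustive=False)
        self.labels_ = part.labels
        self.n_clusters_ = part.n_clusters
        self.observation_chains_ = observation_chains(
            self.chains_.labels, self.chains_.dims
        )
        self.id_summary_ = summarize(self.observation_chains_, part)
        self.cluster_mean_ids_ = np.array(
            [
                self.observation_chains_[:, self.labels_ == l].mean()
                for l in range(self.n_clusters_)
            ]
        )
        self.point_ids_ = self.id_summary_["median_id"].to_numpy()
        self.n_features_in_ = X.shape[1]
        return self
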