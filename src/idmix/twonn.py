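"""Nearest-neighbour geometry and the TWO-NN intrinsic-dimension estimator.

For points sampled with locally homogeneous density on a d-dimensional
manifold, the ratio of each point's second to first nearest-neighbour
distance, mu_i = r_{i,2} / r_{i,1}, follows a Pareto(1, d) law. The maximum
likelihood estimate of d from n ratios is the closed form

    d_hat = n / sum_i log mu_i,        se(d_hat) = d_hat / sqrt(n),

the Gamma-posterior / Fisher-information scale. This module computes exact
Euclidean q-NN distances (brute force — the target panels have ~10^2 rows),
the ratio vector, the single-manifold MLE, and the binary q-neighbourhood
matrix N^(q) used by the heterogeneous mixture model.

Ties in distance are broken by ascending row index (stable sort) so repeated
runs are bit-identical. Duplicate rows are a hard error because a zero first
neighbour distance makes the ratio undefined; an optional seeded jitter at
1e-9 scale is available to break exact duplicates deliberately.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "nn_distances",
    "nn_indices",
    "ratios",
    "twonn_mle",
    "neighbourhood_matrix",
    "jitter_duplicates",
    "TwoNN",
]


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(getattr(X, "values", X), dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D data matrix")
    if not np.isfinite(X).all():
        raise ValueError("data matrix contains NaN/inf")
    return X


def _check_unique(X: np.ndarray) -> None:
    uniq = np.unique(X, axis=0)
    if uniq.shape[0] != X.shape[0]:
        raise ValueError(
            "duplicate rows detected; unique observations are required "
            "(consider jitter_duplicates)"
        )


def jitter_duplicates(X, scale: float = 1e-9, random_state=None) -> np.ndarray:
    """Add uniform noise at ``scale`` to break exact duplicate rows."""
    X = _as_matrix(X)
    rng = np.random.default_rng(random_state)
    return X + rng.uniform(-scale, scale, size=X.shape)


def _nn_order(X: np.ndarray, q: int):
    """(distances, indices) of the first q neighbours per row, ties by index."""
    n = X.shape[0]
    if n < q + 1:
        raise ValueError(f"need at least q+1={q + 1} rows, got {n}")
    _check_unique(X)
    d2 = cdist(X, X, metric="sqeuclidean")
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")[:, :q]
    dist = np.sqrt(np.take_along_axis(d2, order, axis=1))
    return dist, order


def nn_distances(X, q: int = 2) -> np.ndarray:
    """Exact Euclidean distances to each row's first q neighbours (n × q)."""
    return _nn_order(_as_matrix(X), q)[0]


def nn_indices(X, q: int) -> np.ndarray:
    """Indices of each row's first q neighbours (n × q), ties by row index."""
    return _nn_order(_as_matrix(X), q)[1]


def ratios(distances) -> np.ndarray:
    """Second-to-first neighbour distance ratios mu_i = r_{i,2} / r_{i,1}."""
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[1] < 2:
        raise ValueError("need an n × q distance table with q >= 2")
    if (d[:, 0] <= 0).any():
        raise ValueError("zero first-neighbour distance (duplicate rows?)")
    return d[:, 1] / d[:, 0]


def twonn_mle(mu) -> tuple[float, float]:
    """Closed-form Pareto MLE of the intrinsic dimension and its SE."""
    mu = np.asarray(mu, dtype=float)
    if (mu < 1).any():
        raise ValueError("ratios must be >= 1")
    log_sum = float(np.log(mu).sum())
    if log_sum <= 0:
        raise ValueError("all ratios equal 1; estimate diverges")
    d_hat = mu.size / log_sum
    return d_hat, d_hat / np.sqrt(mu.size)


def neighbourhood_matrix(X, q: int) -> np.ndarray:
    """Binary n × n matrix with (i, j) = 1 iff j is among i's first q NNs.

    Zero diagonal, every row sums to exactly q; not necessarily symmetric.
    """
    idx = nn_indices(X, q)
    n = idx.shape[0]
    N = np.zeros((n, n), dtype=np.int8)
    N[np.repeat(np.arange(n), q), idx.ravel()] = 1
    return N


class TwoNN(BaseEstimator):
    """Single-manifold intrinsic-dimension estimator (TWO-NN).

    Parameters
    ----------
    jitter : bool, default=False
        Break exact duplicate rows with seeded uniform noise at 1e-9 scale
        instead of raising.
    random_state : int or None
        Seed for the jitter noise.

    Attributes
    ----------
    dimension_ : float
        Maximum-likelihood intrinsic dimension.
    se_ : float
        Standard error ``dimension_ / sqrt(n)``.
    ratios_ : ndarray of shape (n,)
        The mu_i ratios the fit is based on.
    distances_ : ndarray of shape (n, 2)
        First and second neighbour distances.
    """

    def __init__(self, jitter: bool = False, random_state=None):
        self.jitter = jitter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _as_matrix(X)
        if self.jitter:
            X = jitter_duplicates(X, random_state=self.random_state)
        self.distances_ = nn_distances(X, q=2)
        self.ratios_ = ratios(self.distances_)
        self.dimension_, self.se_ = twonn_mle(self.ratios_)
        self.n_features_in_ = X.shape[1]
        return self

    def score(self, X=None, y=None) -> float:
        """Pareto log-likelihood of the stored ratios at the fitted d."""
        check_is_fitted(self, "dimension_")
        d = self.dimension_
        return float(np.sum(np.log(d) - (d + 1) * np.log(self.ratios_)))
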