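"""Global spatial autocorrelation of per-unit statistics: Moran's I.

With binary contiguity weights w_ij (1 for neighbours, 0 otherwise, zero
diagonal, not row-standardised),

    I = (N / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

where W is the total weight. Under random permutation of x over the units,
E[I] = -1/(N-1); inference is by a permutation test (the analytic normal
approximation is deliberately not offered).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpatialWeights", "build_weights", "morans_i", "permutation_test"]


@dataclass
class SpatialWeights:
    """Binary symmetric contiguity matrix with zero diagonal."""

    matrix: np.ndarray

    def __post_init__(self):
        W = np.asarray(self.matrix)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be square")
        if not np.isin(W, (0, 1)).all():
            raise ValueError("weights must be binary")
        if np.diag(W).any():
            raise ValueError("diagonal must be zero (w_ii = 0)")
        if not (W == W.T).all():
            raise ValueError("contiguity weights must be symmetric")
        isolated = np.flatnonzero(W.sum(axis=1) == 0)
        if isolated.size:
            raise ValueError(f"isolated unit(s) with no neighbour: {isolated.tolist()}")
        self.matrix = W.astype(np.int8)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def total(self) -> int:
        """W: the sum of all weights (each undirected edge counts twice)."""
        return int(self.matrix.sum())

    @classmethod
    def from_edges(cls, edges, n: int) -> "SpatialWeights":
        W = np.zeros((n, n), dtype=np.int8)
        for i, j in edges:
            i, j = int(i), int(j)
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i}, {j}) out of range for n={n}")
            if i == j:
                raise ValueError(f"self-loop ({i}, {i}) rejected: w_ii = 0")
            W[i, j] = W[j, i] = 1
        return cls(W)

    @classmethod
    def read_edgelist(cls, path, n: int | None = None) -> "SpatialWeights":
        edges = np.loadtxt(path, dtype=int, ndmin=2)
        if n is None:
            n = int(edges.max()) + 1
        return cls.from_edges(edges, n)

    def write_edgelist(self, path) -> None:
        i, j = np.nonzero(np.triu(self.matrix))
        np.savetxt(path, np.column_stack([i, j]), fmt="%d", delimiter="\t")


def build_weights(edges, n: int) -> SpatialWeights:
    """Symmetric binary weights from an undirected edge list over 0..n-1."""
    return SpatialWeights.from_edges(edges, n)


def morans_i(x, weights: SpatialWeights) -> float:
    """Exact Moran's I of x under the given binary weights."""
    x = np.asarray(x, dtype=float)
    W = weights.matrix.astype(float)
    if x.size != weights.n:
        raise ValueError("x length does not match the number of spatial units")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("Moran's I undefined for constant x")
    return float(weights.n / weights.total * (z @ W @ z) / denom)


def permutation_test(
    x,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Permutation test of Moran's I.

    Returns (I_obs, p) with p = (1 + #extreme) / (1 + n_perm). ``alternative``
    is 'greater' (positive autocorrelation, the default), 'less' or
    'two-sided'.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError("alternative must be greater, less or two-sided")
    x = np.asarray(x, dtype=float)
    i_obs = morans_i(x, weights)
    rng = np.random.default_rng(seed)
    n = weights.n
    Wf = weights.matrix.astype(float)
    z = x - x.mean()
    denom = float(z @ z)
    scale = n / weights.total / denom
    draws = np.empty(n_perm)
    for b in range(n_perm):
        zp = z[rng.permutation(n)]
        draws[b] = scale * (zp @ Wf @ zp)
    e_null = -1.0 / (n - 1)
    if alternative == "greater":
        extreme = np.sum(draws >= i_obs)
    elif alternative == "less":
        extreme = np.sum(draws <= i_obs)
    else:
        extreme = np.sum(np.abs(draws - e_null) >= abs(i_obs - e_null))
    return i_obs, float((1 + extreme) / (1 + n_perm))
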