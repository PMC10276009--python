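"""Gibbs-sweep kernel for the neighbourhood-augmented Pareto mixture.

The per-point label conditional combines

* the Pareto factor          pi_l * d_l * mu_i^{-(d_l + 1)},
* the out-neighbour factor   zeta^{m_i(l)} (1-zeta)^{q - m_i(l)} for the q
  neighbours of i,
* the in-neighbour factor    one zeta/(1-zeta) Bernoulli term for every j
  that lists i among its q neighbours,
* the normalising constants  Z_j for every point j, which depend on cluster
  sizes: Z(s) = sum_k C(s-1, k) C(n-s, q-k) zeta^k (1-zeta)^{q-k} for a point
  in a cluster of size s. At zeta = 0.5, Z(s) = 0.5^q C(n-1, q) for every s,
  so all neighbourhood terms cancel and the conditional reduces to the plain
  mixture.

The sweep is written in nopython-compatible style; when numba is importable
the function is JIT-compiled, otherwise the pure-Python version runs. All
randomness (sweep order, Gumbel noise) is drawn outside, so the two paths are
bit-identical.
"""

from __future__ import annotations

import numpy as np


def _label_sweep_py(
    order,       # (n,) int64 sweep order
    gumbels,     # (n, L) float64 Gumbel(0,1) noise, row idx follows `order`
    labels,      # (n,) int64, updated in place
    sizes,       # (L,) int64 cluster sizes, updated in place
    logmu,       # (n,) float64 log ratios
    nbr,         # (n, q) int64 out-neighbour indices
    in_ptr,      # (n+1,) int64 CSR pointers of in-neighbour lists
    in_idx,      # (nnz,) int64 CSR indices: points that list i as neighbour
    log_pi,      # (L,) float64
    log_d,       # (L,) float64
    d,           # (L,) float64
    logZ,        # (n+1,) float64 log Z(size), logZ[0] = 0
    log_z,       # float64 log zeta
    log_1mz,     # float64 log (1 - zeta)
):
    L = log_pi.shape[0]
    q = nbr.shape[1]
    m = np.zeros(L, dtype=np.float64)
    r = np.zeros(L, dtype=np.float64)
    for pos in range(order.shape[0]):
        i = order[pos]
        sizes[labels[i]] -= 1
        for l in range(L):
            m[l] = 0.0
            r[l] = 0.0
        for jj in range(q):
            m[labels[nbr[i, jj]]] += 1.0
        R = 0.0
        for p in range(in_ptr[i], in_ptr[i + 1]):
            r[labels[in_idx[p]]] += 1.0
            R += 1.0
        base = 0.0
        for k in range(L):
            base += sizes[k] * logZ[sizes[k]]
        best = -np.inf
        arg = 0
        for l in range(L):
            zsum = (
                base
                - sizes[l] * logZ[sizes[l]]
                + (sizes[l] + 1) * logZ[sizes[l] + 1]
            )
            lp = (
                log_pi[l]
                + log_d[l]
                - (d[l] + 1.0) * logmu[i]
                + (m[l] + r[l]) * log_z
                + (q - m[l] + R - r[l]) * log_1mz
                - zsum
                + gumbels[pos, l]
            )
            if lp > best:
                best = lp
                arg = l
        labels[i] = arg
        sizes[arg] += 1


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _label_sweep = njit(cache=False)(_label_sweep_py)
    HAS_NUMBA = True
except Exception:  # pragma: no cover
    _label_sweep = _label_sweep_py
    HAS_NUMBA = False
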