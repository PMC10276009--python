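"""Label-switching-aware posterior summaries.

A finite mixture with exchangeable components gives chains whose component
labels can permute freely across iterations, so raw per-component summaries
are meaningless. Everything here is built from two relabelling-invariant
objects:

* the posterior co-clustering matrix (PCM), whose (i, j) entry is the
  fraction of kept iterations in which observations i and j share a
  component, and
* the observation-specific dimension chains d_{c_i}, obtained by routing each
  iteration's component-dimension draws through that iteration's labels.

The point-estimate partition minimises the posterior-expected Variation of
Information over a candidate set, using the standard Jensen lower bound that
is computable from the PCM alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "coclustering",
    "expected_vi_lower_bound",
    "vi_partition",
    "observation_chains",
    "summarize",
    "canonical_labels",
    "Partition",
]


@dataclass(frozen=True)
class Partition:
    """A clustering of n observations into L* contiguously-coded clusters."""

    labels: np.ndarray  # (n,) ints in 0..n_clusters-1
    n_clusters: int

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        used = np.unique(labels)
        if not np.array_equal(used, np.arange(self.n_clusters)):
            raise ValueError("labels must use 0..n_clusters-1 contiguously")


def canonical_labels(labels) -> np.ndarray:
    """Recode labels to 0..L*-1 by order of first appearance."""
    labels = np.asarray(labels)
    _, first = np.unique(labels, return_index=True)
    mapping = {labels[i]: rank for rank, i in enumerate(sorted(first))}
    return np.array([mapping[l] for l in labels], dtype=np.int64)


def coclustering(labels_chain) -> np.ndarray:
    """PCM: fraction of iterations in which each pair shares a component."""
    C = np.asarray(labels_chain)
    if C.ndim != 2 or C.shape[0] == 0:
        raise ValueError("labels_chain must be a non-empty (n_kept, n) matrix")
    n_kept, n = C.shape
    pcm = np.zeros((n, n), dtype=np.float64)
    # sum_t 1[c_ti == c_tj] = sum_l (I_l^T I_l) with I_l the (t, i) indicator
    for l in np.unique(C):
        ind = (C == l).astype(np.float64)
        pcm += ind.T @ ind
    pcm /= n_kept
    np.fill_diagonal(pcm, 1.0)
    return pcm


def expected_vi_lower_bound(pcm: np.ndarray, labels) -> float:
    """Jensen lower bound on the posterior-expected VI of a candidate.

    For candidate labels c and co-clustering probabilities p_ij:

        (1/n) * sum_i [ log n_{c_i} + log sum_j p_ij
                        - 2 log sum_{j: c_j = c_i} p_ij ]

    (natural log). Exact zero for a PCM that is the 0/1 matrix of c itself.
    """
    pcm = np.asarray(pcm, dtype=np.float64)
    labels = canonical_labels(labels)
    n = pcm.shape[0]
    L = labels.max() + 1
    onehot = np.zeros((n, L))
    onehot[np.arange(n), labels] = 1.0
    sizes = onehot.sum(axis=0)
    within = (pcm @ onehot)[np.arange(n), labels]  # sum_{j in cluster(i)} p_ij
    total = pcm.sum(axis=1)
    return float(np.mean(np.log(sizes[labels]) + np.log(total) - 2.0 * np.log(within)))


def _all_partitions(n: int):
    """Yield every set partition of range(n) as a label vector (Bell(n) many)."""
    labels = np.zeros(n, dtype=np.int64)

    def rec(i, k):
        if i == n:
            yield labels.copy()
            return
        for l in range(k + 1):
            labels[i] = l
            yield from rec(i + 1, max(k, l + 1))

    yield from rec(1, 1) if n > 1 else iter([labels.copy()])


def vi_partition(pcm, labels_chain=None, exhaustive: str | bool = "auto") -> Partition:
    """Partition minimising the expected-VI lower bound over candidates.

    Candidates are the unique sampled partitions (if a chain is given) plus
    average-linkage cuts of 1 − PCM at every merge height. For n <= 10 (or
    ``exhaustive=True``) all set partitions are searched instead, which is
    exact for the lower-bound objective.
    """
    pcm = np.asarray(pcm, dtype=np.float64)
    n = pcm.shape[0]
    candidates: list[np.ndarray] = []
    if exhaustive is True or (exhaustive == "auto" and n <= 10):
        candidates.extend(_all_partitions(n))
    else:
        dist = 1.0 - pcm
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        heights = np.unique(Z[:, 2])
        for h in np.concatenate(([-(1e-12)], heights)):
            candidates.append(fcluster(Z, t=h, criterion="distance") - 1)
        if labels_chain is not None:
            C = np.asarray(labels_chain)
            canon = np.stack([canonical_labels(row) for row in C])
            candidates.extend(np.unique(canon, axis=0))
    best, best_loss = None, np.inf
    for cand in candidates:
        loss = expected_vi_lower_bound(pcm, cand)
        if loss < best_loss - 1e-12:
            best, best_loss = canonical_labels(cand), loss
    return Partition(best, int(best.max()) + 1)


def observation_chains(labels_chain, dims_chain) -> np.ndarray:
    """Map L component chains to n observation chains: (t, i) -> d_{c_ti}."""
    C = np.asarray(labels_chain)
    D = np.asarray(dims_chain, dtype=np.float64)
    if C.shape[0] != D.shape[0]:
        raise ValueError("chains not aligned by iteration")
    if C.min() < 0 or C.max() >= D.shape[1]:
        raise ValueError(f"labels out of range 0..{D.shape[1] - 1}")
    return np.take_along_axis(D, C, axis=1)


def summarize(obs_chains, partition: Partition, units=None) -> pd.DataFrame:
    """Per-observation posterior ID summaries plus cluster assignment.

    Columns: median_id, q05, q95 (central 90% interval), cluster,
    cluster_mean_id (posterior mean pooled over the draws of every member of
    the observation's cluster).
    """
    O = np.asarray(obs_chains, dtype=np.float64)
    labels = partition.labels
    if O.shape[1] != labels.size:
        raise ValueError("chains and partition not aligned")
    med = np.median(O, axis=0)
    q05 = np.quantile(O, 0.05, axis=0)
    q95 = np.quantile(O, 0.95, axis=0)
    cluster_mean = np.empty(partition.n_clusters)
    for l in range(partition.n_clusters):
        cluster_mean[l] = O[:, labels == l].mean()
    index = np.arange(labels.size) if units is None else list(units)
    return pd.DataFrame(
        {
            "median_id": med,
            "q05": q05,
            "q95": q95,
            "cluster": labels,
            "cluster_mean_id": cluster_mean[labels],
        },
        index=index,
    )
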