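"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators:

* multi-manifold point clouds — samples of known intrinsic dimension
  (isotropic Gaussian clouds by default, uniform unit hypercubes on request),
  zero-padded into the nominal dimension, rotated by a seeded random
  orthogonal matrix and offset so components are well separated; this
  realises the locally-homogeneous-density setting in which the TWO-NN
  Pareto law holds, with known ground-truth labels and dimensions;
* synthetic country panels — per-unit daily series driven by a small number
  of shared latent factors with unit-specific loadings (so the concatenated
  matrix has known low rank), optional MCAR missingness and, optionally,
  manifold membership constant on the communities of a spatial neighbour
  graph so that the resulting ID map is spatially autocorrelated by
  construction;
* spatial adjacency — grid or random-geometric contiguity graphs in which
  every unit is guaranteed at least one neighbour.

All randomness flows through one ``numpy.random.default_rng(seed)`` per
call, so identical specs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import ortho_group

from .panel import CountryPanel
from .spatial import SpatialWeights

__all__ = [
    "ManifoldSpec",
    "PanelSpec",
    "sample_manifold_mixture",
    "synth_country_panel",
    "synth_adjacency",
]


@dataclass(frozen=True)
class ManifoldSpec:
    """Mixture of d-dimensional components embedded in ``nominal_dim``.

    ``components`` is a list of (intrinsic_dim, n_points) pairs. Two
    primitives are available: ``"gaussian"`` (default), an isotropic standard
    normal cloud, and ``"cube"``, a uniform unit hypercube. The Gaussian is
    boundaryless, so the TWO-NN Pareto law holds essentially without bias at
    the sample sizes used here; the bounded cube suffers a downward
    edge-effect bias that grows with d (clearly visible for d >= 8) and is
    kept for low-dimensional checks. Components are offset from each other by
    ``separation`` along the first embedding axis (default 10 unit lengths)
    so that q-NN neighbourhoods stay pure.
    """

    components: tuple
    nominal_dim: int
    separation: float = 10.0
    noise_sd: float = 0.0
    primitive: str = "gaussian"
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(tuple(c) for c in self.components))
        if not self.components:
            raise ValueError("need at least one component")
        for d, npts in self.components:
            if d < 1 or d > self.nominal_dim:
                raise ValueError(f"intrinsic dim {d} must be in 1..{self.nominal_dim}")
            if npts < 3:
                raise ValueError("each component needs n_points >= 3 (TWO-NN needs two neighbours)")
        if self.separation < 0 or self.noise_sd < 0:
            raise ValueError("separation and noise_sd must be non-negative")
        if self.primitive not in ("gaussian", "cube"):
            raise ValueError("primitive must be 'gaussian' or 'cube'")


def sample_manifold_mixture(spec: ManifoldSpec):
    """Sample the mixture; returns (matrix, true_labels, true_dims).

    ``matrix`` is (sum n_points) × nominal_dim with distinct rows;
    ``true_labels`` gives each row's component (0-based); ``true_dims`` the
    per-component intrinsic dimensions.
    """
    rng = np.random.default_rng(spec.seed)
    D = spec.nominal_dim
    blocks, labels = [], []
    for k, (d, npts) in enumerate(spec.components):
        if spec.primitive == "cube":
            core = rng.uniform(0.0, 1.0, size=(npts, d))
        else:
            core = rng.standard_normal(size=(npts, d))
        padded = np.zeros((npts, D))
        padded[:, :d] = core
        rot = ortho_group.rvs(D, random_state=rng) if D > 1 else np.ones((1, 1))
        pts = padded @ rot.T
        pts[:, 0] += k * spec.separation
        blocks.append(pts)
        labels.append(np.full(npts, k, dtype=np.int64))
    X = np.vstack(blocks)
    if spec.noise_sd > 0:
        X = X + rng.normal(0.0, spec.noise_sd, size=X.shape)
    labels = np.concatenate(labels)
    if np.unique(X, axis=0).shape[0] != X.shape[0]:  # pragma: no cover
        raise RuntimeError("degenerate sample: duplicate rows")
    dims = np.array([d for d, _ in spec.components], dtype=np.int64)
    return X, labels, dims


@dataclass(frozen=True)
class PanelSpec:
    """Synthetic country-panel settings.

    ``graph`` is an edge list over unit indices; with ``spatial_field`` on,
    manifold membership is constant on the graph's communities and every
    unit must have at least one neighbour. Membership is obtained by cutting
    the graph into (at most) ``n_groups`` modularity communities; community g
    draws its series from ``latent_dim + g * latent_dim_step`` shared factors
    (capped at the series length), so distinct communities lie on manifolds
    of distinct intrinsic dimension and the resulting ID map is spatially
    autocorrelated by construction. ``group_sep`` scales a per-community mean
    path that keeps the community manifolds apart, so nearest-neighbour
    neighbourhoods stay community-pure.
    """

    n_units: int
    n_days: int
    n_variables: int = 3
    latent_dim: int = 3
    latent_dim_step: int = 4
    n_groups: int = 2
    group_sep: float = 3.0
    missing_rate: float = 0.0
    graph: tuple = ()
    spatial_field: bool = False
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "graph", tuple(tuple(e) for e in self.graph))
        if self.n_units < 1 or self.n_days < 1 or self.n_variables < 1:
            raise ValueError("panel dimensions must be positive")
        if self.latent_dim > self.n_days * self.n_variables:
            raise ValueError("latent_dim cannot exceed n_days * n_variables")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")


def _communities(spec: PanelSpec) -> np.ndarray:
    G = nx.Graph()
    G.add_nodes_from(range(spec.n_units))
    G.add_edges_from(spec.graph)
    isolated = [u for u in G.nodes if G.degree(u) == 0]
    if isolated:
        raise ValueError(f"spatial_field requires no isolated units; isolated: {isolated}")
    best_n = min(spec.n_groups, spec.n_units)
    comms = nx.community.greedy_modularity_communities(G, cutoff=1, best_n=best_n)
    membership = np.empty(spec.n_units, dtype=np.int64)
    for k, comm in enumerate(comms):
        membership[list(comm)] = k
    return membership


def synth_country_panel(spec: PanelSpec):
    """Generate a factor-model panel; returns (panel, true_membership).

    Each membership group has its own latent factor paths F (latent_dim ×
    n_variables·n_days); a unit's concatenated series is its loading vector
    times its group's factors, plus optional observation noise. With zero
    noise the concatenated matrix of any single group has rank at most
    ``latent_dim``. Missing entries are inserted completely at random.
    """
    rng = np.random.default_rng(spec.seed)
    T = spec.n_days * spec.n_variables
    membership = (
        _communities(spec) if spec.spatial_field else np.zeros(spec.n_units, dtype=np.int64)
    )
    n_groups = int(membership.max()) + 1
    group_dims = [
        min(spec.latent_dim + g * spec.latent_dim_step, T) for g in range(n_groups)
    ]
    X = np.empty((spec.n_units, T))
    for g in range(n_groups):
        dim_g = group_dims[g]
        factors = rng.standard_normal(size=(dim_g, T))
        members = np.flatnonzero(membership == g)
        loadings = rng.standard_normal(size=(members.size, dim_g))
        mean_g = spec.group_sep * rng.standard_normal(T) if n_groups > 1 else 0.0
        X[members] = mean_g + loadings @ factors  # manifold of dimension dim_g
    if spec.noise_sd > 0:
        X = X + rng.normal(0.0, spec.noise_sd, size=X.shape)
    if spec.missing_rate > 0:
        mask = rng.uniform(size=X.shape) < spec.missing_rate
        X = np.where(mask, np.nan, X)
    units = [f"U{u:03d}" for u in range(spec.n_units)]
    dates = pd.date_range("2020-03-01", periods=spec.n_days, freq="D")
    variables = {}
    for v in range(spec.n_variables):
        tab = pd.DataFrame(
            X[:, v * spec.n_days : (v + 1) * spec.n_days], index=units, columns=dates
        )
        variables[f"var{v + 1}"] = tab
    population = pd.Series(
        np.round(rng.lognormal(mean=16.0, sigma=1.0, size=spec.n_units)),
        index=units,
        name="population",
    )
    return CountryPanel(variables, population=population), membership


def synth_adjacency(n_units: int, model: str = "grid", seed: int = 0) -> SpatialWeights:
    """Contiguity weights from a grid or random-geometric graph.

    Every unit ends up with at least one neighbour: in the random-geometric
    model, an isolated node is connected to its nearest unit by centroid
    distance before the matrix is returned.
    """
    if n_units < 2:
        raise ValueError("need at least 2 units")
    rng = np.random.default_rng(seed)
    if model == "grid":
        side = int(np.ceil(np.sqrt(n_units)))
        G = nx.grid_2d_graph(side, side)
        nodes = sorted(G.nodes)[:n_units]
        G = G.subgraph(nodes)
        relabel = {node: i for i, node in enumerate(sorted(G.nodes))}
        edges = [(relabel[a], relabel[b]) for a, b in G.edges]
    elif model == "random-geometric":
        radius = 1.5 / np.sqrt(n_units)
        pos = rng.uniform(size=(n_units, 2))
        G = nx.random_geometric_graph(n_units, radius, pos={i: p for i, p in enumerate(pos)})
        edges = list(G.edges)
        degree = np.zeros(n_units, dtype=int)
        for a, b in edges:
            degree[a] += 1
            degree[b] += 1
        for u in np.flatnonzero(degree == 0):
            d2 = ((pos - pos[u]) ** 2).sum(axis=1)
            d2[u] = np.inf
            v = int(np.argmin(d2))
            edges.append((u, v))
            degree[u] += 1
            degree[v] += 1
    else:
        raise ValueError("model must be 'grid' or 'random-geometric'")
    return SpatialWeights.from_edges(edges, n_units)
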