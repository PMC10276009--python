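"""Panel preprocessing: availability filters, imputation, pooled z-scoring,
concatenation into the analysis matrix, and temporal stratification.

The canonical order is::

    filter_missing -> impute -> filter_population -> standardize -> concatenate

which :class:`PanelPipeline` runs end to end. Each variable is z-scored
against its own pooled mean and sample standard deviation computed across all
units and all days, so that the three series are on a common scale before
nearest-neighbour distances are taken. The per-unit concatenated rows
(variable 1 days, then variable 2 days, ...) form the n × D analysis matrix
whose nominal dimension is D = n_variables × n_days.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import CountryPanel, StandardizedPanel, StageWindow

__all__ = [
    "filter_missing",
    "impute_linear",
    "impute_panel",
    "filter_population",
    "standardize",
    "concatenate",
    "stratify",
    "dimensionality_reduction_pct",
    "PanelPipeline",
]


def filter_missing(panel: CountryPanel, max_missing_frac: float = 0.2):
    """Drop units with more than ``max_missing_frac`` missing in any variable.

    A unit survives iff, for *every* variable, its fraction of missing days is
    <= ``max_missing_frac`` (strictly-greater fractions are excluded).

    Returns
    -------
    (panel, exclusions)
        The retained sub-panel and a dict mapping each excluded unit to the
        per-variable missing fractions that caused its exclusion.
    """
    n_days = panel.n_days
    exclusions: dict = {}
    for name, tab in panel.variables.items():
        frac = tab.isna().sum(axis=1) / n_days
        for unit in frac.index[frac > max_missing_frac]:
            exclusions.setdefault(unit, {})[name] = float(frac.loc[unit])
    keep = [u for u in panel.units if u not in exclusions]
    if not keep:
        raise ValueError("no units survive the missingness filter")
    return panel.subset_units(keep), exclusions


def impute_linear(series, time_index=None) -> np.ndarray:
    """Fill missing entries with an OLS line of value on time index.

    The line is fitted on the observed (time, value) pairs only and evaluated
    at the missing time points, so leading/trailing gaps are extrapolated.
    Observed entries are returned unchanged.
    """
    y = np.asarray(series, dtype=float)
    t = np.arange(y.size) if time_index is None else np.asarray(time_index, dtype=float)
    if t.size != y.size:
        raise ValueError("time_index length mismatch")
    obs = ~np.isnan(y)
    if obs.sum() < 2:
        raise ValueError("need at least 2 observed points to impute")
    if np.ptp(t[obs]) == 0:
        raise ValueError("constant time index among observed points")
    slope, intercept = np.polyfit(t[obs], y[obs], deg=1)
    out = y.copy()
    out[~obs] = slope * t[~obs] + intercept
    return out


def impute_panel(panel: CountryPanel, method: str = "ols") -> CountryPanel:
    """Impute every unit × variable series; ``method`` is 'ols' or 'interp'."""
    if method not in ("ols", "interp"):
        raise ValueError("method must be 'ols' or 'interp'")
    variables = {}
    for name, tab in panel.variables.items():
        tab = tab.copy()
        if method == "ols":
            for unit in tab.index:
                row = tab.loc[unit].to_numpy(dtype=float)
                if np.isnan(row).any():
                    tab.loc[unit] = impute_linear(row)
        else:
            tab = tab.interpolate(axis=1, limit_direction="both")
        variables[name] = tab
    return CountryPanel(variables, population=panel.population)


def filter_population(panel: CountryPanel, min_pop: int = 1_000_000):
    """Drop units with population strictly below ``min_pop``.

    Small populations make per-million rates volatile; a strict ``<`` keeps a
    unit at exactly the threshold. Returns ``(panel, excluded_units)``.
    """
    if panel.population is None:
        raise ValueError("population metadata required")
    bad = panel.population.index[panel.population.isna()]
    if len(bad):
        raise ValueError(f"population missing for unit(s): {list(bad)}")
    keep = [u for u in panel.units if panel.population.loc[u] >= min_pop]
    excluded = [u for u in panel.units if u not in set(keep)]
    if not keep:
        raise ValueError("no units survive the population filter")
    return panel.subset_units(keep), excluded


def standardize(panel: CountryPanel) -> StandardizedPanel:
    """Z-score each variable against its pooled mean/SD over all units × days.

    Uses the sample (n−1) standard deviation. Requires a complete panel and
    non-constant variables.
    """
    variables, means, sds = {}, {}, {}
    for name, tab in panel.variables.items():
        vals = tab.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"variable {name!r} still has missing values")
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if sd == 0:
            raise ValueError(f"variable {name!r} is constant (zero pooled SD)")
        variables[name] = (tab - mean) / sd
        means[name], sds[name] = mean, sd
    return StandardizedPanel(variables, population=panel.population, means=means, sds=sds)


def concatenate(panel: CountryPanel) -> pd.DataFrame:
    """One row per unit; columns are var-1 days, var-2 days, ... (n × D).

    Column labels are ``"{variable}:{t}"`` with t the 0-based day offset.
    Duplicate rows are a hard error (the mixture model needs unique points)
    naming the offending unit pairs.
    """
    blocks, columns = [], []
    for name, tab in panel.variables.items():
        vals = tab.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"variable {name!r} has missing values; impute first")
        blocks.append(vals)
        columns.extend(f"{name}:{t}" for t in range(tab.shape[1]))
    mat = pd.DataFrame(np.hstack(blocks), index=panel.units, columns=columns)
    _, inverse, counts = np.unique(
        mat.to_numpy(), axis=0, return_inverse=True, return_counts=True
    )
    if (counts > 1).any():
        pairs = []
        for g in np.flatnonzero(counts > 1):
            members = [panel.units[i] for i in np.flatnonzero(inverse == g)]
            pairs.append(tuple(members))
        raise ValueError(f"duplicate rows for unit groups: {pairs}")
    return mat


def stratify(panel: CountryPanel, windows: list[StageWindow]) -> list[CountryPanel]:
    """Split the panel into one sub-panel per window (inclusive bounds).

    The windows must partition the panel's date range exactly — no gaps, no
    overlaps.
    """
    windows = sorted(windows, key=lambda w: w.start)
    dates = panel.dates
    if pd.Timestamp(windows[0].start) != dates[0] or pd.Timestamp(windows[-1].end) != dates[-1]:
        raise ValueError("windows do not span the panel's date range")
    for prev, nxt in zip(windows, windows[1:]):
        gap = (nxt.start - prev.end).days
        if gap != 1:
            kind = "overlap" if gap < 1 else "gap"
            raise ValueError(
                f"{kind} between window {prev.label} (ends {prev.end}) "
                f"and window {nxt.label} (starts {nxt.start})"
            )
    return [panel.subset_dates(w.start, w.end) for w in windows]


def dimensionality_reduction_pct(intrinsic_dim: float, nominal_dim: int) -> float:
    """Percentage of nominal dimensions shed: 100 × (1 − d/D)."""
    return 100.0 * (1.0 - intrinsic_dim / nominal_dim)


class PanelPipeline:
    """Filter → impute → filter → standardize → concatenate, in one object.

    Parameters mirror the individual steps. After :meth:`run`, the fitted
    state (exclusion logs, pooled moments) is available as attributes with a
    trailing underscore.
    """

    def __init__(
        self,
        max_missing_frac: float = 0.2,
        min_pop: int | None = 1_000_000,
        impute: str = "ols",
    ):
        self.max_missing_frac = max_missing_frac
        self.min_pop = min_pop
        self.impute = impute

    def run(self, panel: CountryPanel) -> pd.DataFrame:
        panel, self.missing_exclusions_ = filter_missing(panel, self.max_missing_frac)
        panel = impute_panel(panel, method=self.impute)
        if self.min_pop is not None and panel.population is not None:
            panel, self.population_exclusions_ = filter_population(panel, self.min_pop)
        else:
            self.population_exclusions_ = []
        std = standardize(panel)
        self.means_, self.sds_ = std.means, std.sds
        self.panel_ = std
        return concatenate(std)
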