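import numpy as np
import pandas as pd
import pytest

from idmix import Hidalgo
from idmix.panel import CountryPanel
from idmix.synthetic import ManifoldSpec, sample_manifold_mixture


@pytest.fixture(scope="session")
def two_manifold_data():
    """Two well-separated components of intrinsic dimension 2 and 8."""
    spec = ManifoldSpec(components=[(2, 300), (8, 300)], nominal_dim=20, seed=3)
    X, labels, dims = sample_manifold_mixture(spec)
    return X, labels, dims


@pytest.fixture(scope="session")
def two_manifold_fit(two_manifold_data):
    """Sparse-mixture fit on the two-manifold sample (shared across tests)."""
    X, labels, dims = two_manifold_data
    model = Hidalgo(L=6, alpha=0.05, n_iter=5000, burn_in=1000, random_state=4)
    model.fit(X)
    return model, labels, dims


def make_panel(values, population=None, start="2020-03-01"):
    """Build a CountryPanel from {variable: 2-D array} over synthetic units."""
    first = next(iter(values.values()))
    n_units, n_days = np.asarray(first).shape
    units = [f"U{i}" for i in range(n_units)]
    dates = pd.date_range(start, periods=n_days, freq="D")
    variables = {
        k: pd.DataFrame(np.asarray(v, dtype=float), index=units, columns=dates)
        for k, v in values.items()
    }
    pop = None
    if population is not None:
        pop = pd.Series(np.asarray(population, dtype=float), index=units)
    return CountryPanel(variables, population=pop)
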