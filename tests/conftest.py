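import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import spatialrf as s

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def checkerboard():
    """2x2 rook lattice with the +1/-1 checkerboard field."""
    return s.lattice_rook(2, 2), np.array([1.0, -1.0, -1.0, 1.0])


@pytest.fixture
def chain4():
    """1x4 chain A-B-C-D."""
    return s.lattice_rook(1, 4)


def make_dataset(n=50, p=2, seed=0, slope=2.0, noise=0.5, centroids=False):
    """Simple non-spatial regression dataset: y = slope * x1 + noise."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = slope * X[:, 0] + noise * rng.standard_normal(n)
    cen = rng.uniform(0, 10, size=(n, 2)) if centroids else None
    return s.AreaDataset(
        tuple(f"g{i}" for i in range(n)),
        pd.Series(y, name="y"),
        pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(p)]),
        centroids=cen,
    )


@pytest.fixture
def regression_dataset():
    return make_dataset()
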