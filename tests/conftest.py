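import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from foodaccess.config import CountyConfig
from foodaccess.synthetic import generate_county, generate_tracts
from foodaccess.weights import queen_weights


@pytest.fixture(scope="session")
def small_config():
    """12x12 county (144 tracts, 9 SRAs) — quick but structurally complete."""
    return CountyConfig(seed=11, n_rows=12, n_cols=12, sra_block=4)


@pytest.fixture(scope="session")
def small_county(small_config):
    return generate_county(small_config)


@pytest.fixture(scope="session")
def grid_weights(small_county):
    return small_county.weights  # queen, row-standardized


def make_grid_tracts(n_rows, n_cols, side=1.0):
    """Bare square-grid tract table (ids + geometry only)."""
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    return pd.DataFrame(
        {
            "tract_id": [f"CT{i:04d}" for i in range(n_rows * n_cols)],
            "geometry": [
                box(c * side, r * side, (c + 1) * side, (r + 1) * side)
                for r, c in zip(rows, cols)
            ],
        }
    )


def rook_checkerboard(n):
    """Rook-adjacency binary weights on an n x n grid plus the +-1
    checkerboard values, for closed-form Moran checks."""
    from foodaccess.weights import SpatialWeights

    ids = tuple(f"C{i:03d}" for i in range(n * n))
    neighbors = []
    for i in range(n * n):
        r, c = divmod(i, n)
        nb = []
        if r > 0:
            nb.append(i - n)
        if r < n - 1:
            nb.append(i + n)
        if c > 0:
            nb.append(i - 1)
        if c < n - 1:
            nb.append(i + 1)
        neighbors.append(tuple(nb))
    values = tuple(tuple(1.0 for _ in nb) for nb in neighbors)
    w = SpatialWeights(ids, tuple(neighbors), values, scheme="custom")
    x = np.array([(-1.0) ** ((i // n) + (i % n)) for i in range(n * n)])
    return w, x


def moran_bruteforce(x, w):
    """Independent double-loop oracle for Moran's I."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    z = x - x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j, wij in zip(w.neighbors[i], w.values[i]):
            num += wij * z[i] * z[j]
            s0 += wij
    return (n / s0) * num / (z @ z).item()
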