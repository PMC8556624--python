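import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from acprev.io import PolygonLayer
from acprev.synthetic import GeographySpec, make_geography


@pytest.fixture(scope="session")
def small_geography():
    """2 states x 2 districts x 4 ACs x 3 clusters/AC, fixed seed."""
    return make_geography(GeographySpec(2, 2, 4, 3), seed=11)


@pytest.fixture()
def unit_grid_layer():
    """3x3 grid of unit squares with ids g00..g22 (row-major)."""
    rows, geoms = [], []
    for r in range(3):
        for c in range(3):
            rows.append({"ac_id": f"g{r}{c}"})
            geoms.append(box(c, r, c + 1, r + 1))
    return PolygonLayer(pd.DataFrame(rows), geoms)


def brute_force_moran(x, w):
    """O(n^2) double-loop Moran's I oracle."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xbar = x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * (x[i] - xbar) * (x[j] - xbar)
            s0 += w[i, j]
    den = ((x - xbar) ** 2).sum()
    return n / s0 * num / den
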