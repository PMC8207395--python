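import numpy as np
import pandas as pd
import pytest

from nestscape.grids import Raster
from nestscape.mlpe import enumerate_pairs


@pytest.fixture
def small_landscape():
    from nestscape.synthetic import generate_landscape

    return generate_landscape(seed=1, n_rows=100, n_cols=100, cell_size=30.0, n_classes=5, smoothing=3.0)


@pytest.fixture
def scattered_individuals():
    """30 individuals at 30 distinct locations (no within-location pairs)."""
    rng = np.random.default_rng(42)
    n = 30
    return pd.DataFrame(
        {
            "id": [f"i{k:02d}" for k in range(n)],
            "location_id": [f"L{k:02d}" for k in range(n)],
            "x": rng.uniform(0, 10_000, n),
            "y": rng.uniform(0, 10_000, n),
        }
    )


@pytest.fixture
def scattered_pairs(scattered_individuals):
    return enumerate_pairs(scattered_individuals)


@pytest.fixture
def uniform_raster():
    return Raster(np.ones((5, 5)), cell_size=1.0)


def dense_commute_matrix(lap: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Independent commute-time oracle: Moore-Penrose pseudo-inverse of the
    full Laplacian, C(i,j) = vol * (L+_ii + L+_jj - 2 L+_ij)."""
    volume = np.trace(lap)
    pinv = np.linalg.pinv(lap)
    m = len(nodes)
    out = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            i, j = nodes[a], nodes[b]
            out[a, b] = volume * (pinv[i, i] + pinv[j, j] - 2 * pinv[i, j])
    return out
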