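import numpy as np
import pytest

from nucleimap.grids import Grid
from nucleimap import synthdata as sd


@pytest.fixture(scope="session")
def small_grid() -> Grid:
    """16^3 1-mm grid centred on the origin, for brute-force oracles."""
    return Grid.isotropic((16, 16, 16), origin_mm=(-8.0, -8.0, -8.0))


@pytest.fixture(scope="session")
def jittered_atlas() -> sd.SyntheticAtlasResult:
    """Ten-subject jittered label fixture on the default reference grid."""
    return sd.gen_subject_labels(sd.default_atlas_spec(seed=11))


@pytest.fixture(scope="session")
def default_db() -> sd.SyntheticDatabase:
    """Coordinate database with the default planted links."""
    return sd.gen_experiment_db(sd.default_database_spec(seed=7, n_experiments=500))


def polygon_perimeter(vertices: np.ndarray) -> float:
    """Independent perimeter: explicit edge-length sum over the vertex list."""
    v = np.asarray(vertices, float)
    total = 0.0
    for i in range(len(v)):
        dx = v[(i + 1) % len(v)] - v[i]
        total += float(np.hypot(dx[0], dx[1]))
    return total
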