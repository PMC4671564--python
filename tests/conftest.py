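import numpy as np
import pytest

import reefconnect as rc
from reefconnect.seascape import HabitatGrid, ReefUnit


@pytest.fixture(scope="session")
def small_config():
    return rc.SeascapeConfig(rng_seed=42, n_reef_clusters=6)


@pytest.fixture(scope="session")
def small_seascape(small_config):
    """40x40 synthetic seascape with six well-separated reef units."""
    return rc.generate_seascape(small_config)


@pytest.fixture(scope="session")
def bio_params():
    return rc.BioParams()


def make_unit(unit_id, cells, areas, eez=0, eco=0, cost=1.0, mpa=0.0):
    rows = [r for r, _ in cells]
    cols = [c for _, c in cells]
    return ReefUnit(
        unit_id=unit_id,
        member_cells=list(cells),
        total_reef_area_km2=float(np.sum(areas)),
        centroid=(float(np.mean(rows)), float(np.mean(cols))),
        eez_id=eez,
        ecoregion_id=eco,
        unit_cost=cost,
        mpa_reef_area_km2=mpa,
    )


def habitat_from_units(shape, units, cell_size_km=8.0, areas_by_cell=None):
    grid = np.zeros(shape)
    for u in units:
        for k, (r, c) in enumerate(u.member_cells):
            if areas_by_cell is not None:
                grid[r, c] = areas_by_cell[u.unit_id][k]
            else:
                grid[r, c] = u.total_reef_area_km2 / len(u.member_cells)
    return HabitatGrid(
        reef_area_km2=grid,
        land_mask=np.zeros(shape, dtype=bool),
        cell_size_km=cell_size_km,
    )


@pytest.fixture
def eez_fixture():
    """Three units (two in EEZ 0, one in EEZ 1) with a fully known matrix."""
    units = [
        make_unit(1, [(0, 0)], [4.0], eez=0, eco=0),
        make_unit(2, [(0, 2)], [4.0], eez=0, eco=0),
        make_unit(3, [(2, 0)], [4.0], eez=1, eco=1),
    ]
    matrix = rc.ConnectivityMatrix(
        settled=np.array([[1.0, 2.0, 3.0], [0.0, 1.0, 1.0], [4.0, 0.0, 2.0]]),
        released=np.array([10.0, 10.0, 10.0]),
        unit_ids=[1, 2, 3],
    )
    return units, matrix
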