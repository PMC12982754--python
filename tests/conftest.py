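"""Shared fixtures: small synthetic datasets built at test time."""

import numpy as np
import pandas as pd
import pytest

from exposcreen import geo, spatial, synthetic
from exposcreen.nonspatial import AGE_BIN_COLUMNS


def make_zips(n=8, seed=0, lat0=40.0, lon0=-85.0, spread=0.5):
    """A small hand-sized zip table with all covariate columns."""
    rng = np.random.default_rng(seed)
    zips = pd.DataFrame(
        {
            "zip_id": [f"Z{i:05d}" for i in range(n)],
            "lat": lat0 + rng.uniform(-spread, spread, n),
            "lon": lon0 + rng.uniform(-spread, spread, n),
            "population": rng.integers(15_000, 80_000, n),
            "deprivation_index": rng.normal(100, 15, n),
            "pop_density": rng.lognormal(6, 1, n),
        }
    )
    age = rng.dirichlet(np.full(21, 8.0), size=n)
    for j, col in enumerate(AGE_BIN_COLUMNS):
        zips[col] = age[:, j]
    return zips


@pytest.fixture
def small_zips():
    return make_zips()


@pytest.fixture(scope="session")
def sim_bundle():
    """One full synthetic dataset with planted effects, reused read-only."""
    planted = tuple((f"CHEM_{i:03d}", "F90.0", 0.8) for i in range(4))
    config = synthetic.SimulationConfig(seed=7, planted_effects=planted)
    zips = synthetic.simulate_geography(config)
    releases = synthetic.simulate_releases(config, zips)
    exposure = geo.build_air_exposure(zips, releases)
    hierarchy = spatial.build_cluster_hierarchy(zips)
    counts, totals = synthetic.simulate_diagnoses(config, zips, exposure, hierarchy)
    return {
        "config": config,
        "zips": zips,
        "releases": releases,
        "exposure": exposure,
        "hierarchy": hierarchy,
        "counts": counts,
        "totals": totals,
    }
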