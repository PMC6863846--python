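import numpy as np
import pandas as pd
import pytest

from karstflora.spatial_grid import EqualAreaGrid, PlanarKm
from karstflora.synthetic_data import LandscapeSpec, gen_occurrences, gen_species_pool


@pytest.fixture(scope="session")
def small_spec() -> LandscapeSpec:
    """Desk-scale landscape: 8x6 cells of 50 km, 120 species."""
    return LandscapeSpec(width_km=400, height_km=300, n_species=120,
                         n_records=6000, seed=42)


@pytest.fixture(scope="session")
def small_pool(small_spec):
    return gen_species_pool(small_spec)


@pytest.fixture(scope="session")
def small_records(small_pool, small_spec) -> pd.DataFrame:
    df = gen_occurrences(small_pool, small_spec)
    df = df.copy()
    df["accepted_name"] = df["verbatim_name"]
    return df


@pytest.fixture(scope="session")
def grid50() -> EqualAreaGrid:
    return EqualAreaGrid(0.0, 0.0, 50.0, PlanarKm())


@pytest.fixture(scope="session")
def grid10() -> EqualAreaGrid:
    return EqualAreaGrid(0.0, 0.0, 10.0, PlanarKm())


def random_layout(rng: np.random.Generator, n_species=40, n_cells=25,
                  n_records=400) -> pd.DataFrame:
    """Random occurrence layout on an anonymous 5x5-ish planar grid."""
    sp = rng.integers(0, n_species, n_records)
    cells = rng.integers(0, n_cells, n_records)
    side = int(np.ceil(np.sqrt(n_cells)))
    return pd.DataFrame({
        "accepted_name": [f"sp{j}" for j in sp],
        "x_km": (cells % side) * 50.0 + rng.uniform(0, 50, n_records),
        "y_km": (cells // side) * 50.0 + rng.uniform(0, 50, n_records),
    })
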