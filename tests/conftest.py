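import numpy as np
import pandas as pd
import pytest

from ecofilter.data_model import CommunityMatrix, SiteTable, TraitTable
from ecofilter.synthetic import SimulationSpec, simulate_study


@pytest.fixture
def toy_traits() -> TraitTable:
    df = pd.DataFrame(
        {
            "body_size": [2.0, 4.0, 6.0],
            "native_status": ["native", "non_native", "native"],
            "diet_type": ["aphids", "aphids", "spiders"],
        },
        index=["A", "B", "C"],
    )
    spec = {
        "body_size": {"kind": "continuous", "weight": 1.0},
        "native_status": {"kind": "nominal", "weight": 1.0},
        "diet_type": {"kind": "nominal", "weight": 1.0},
    }
    return TraitTable(df, spec)


@pytest.fixture
def toy_community() -> CommunityMatrix:
    abund = np.array([[2, 1, 1], [0, 3, 2], [1, 0, 4]])
    years = {s: frozenset({2011, 2012, 2013}) for s in ["s1", "s2", "s3"]}
    return CommunityMatrix(["s1", "s2", "s3"], ["A", "B", "C"], abund, years)


@pytest.fixture
def toy_sites() -> SiteTable:
    df = pd.DataFrame(
        {
            "ugs_type": ["home_garden", "green_roof", "public_park"],
            "impervious_250": [0.5, 0.8, 0.1],
            "open_green_250": [0.3, 0.1, 0.5],
            "closed_green_250": [0.2, 0.1, 0.4],
            "impervious_500": [0.45, 0.75, 0.15],
            "open_green_500": [0.35, 0.15, 0.45],
            "closed_green_500": [0.2, 0.1, 0.4],
            "x": [0.0, 1000.0, 2000.0],
            "y": [0.0, 500.0, 1500.0],
        },
        index=["s1", "s2", "s3"],
    )
    return SiteTable(df, (250, 500))


@pytest.fixture(scope="session")
def small_study():
    """A modest neutral study reused by several test modules."""
    spec = SimulationSpec(n_sites=60, n_species=20, seed=42,
                          filtering_strength=0.0)
    return simulate_study(spec)


@pytest.fixture(scope="session")
def filtered_study():
    """A strongly filtered study (clear trait-environment coupling)."""
    spec = SimulationSpec(n_sites=60, n_species=20, seed=7,
                          filtering_strength=20.0,
                          trait_optimum_coupling=0.8)
    return simulate_study(spec)
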