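import warnings

import numpy as np
import pandas as pd
import pytest

from phylochem.datatypes import ChemProfileMatrix, SampleTable, SequenceAlignment
from phylochem.simulate import LocusConfig, SimulationConfig, simulate_dataset


@pytest.fixture
def tiny_alignment() -> SequenceAlignment:
    return SequenceAlignment(
        "coi-like",
        ["a", "b", "c", "d"],
        ["AAATTT", "AAATTT", "AAGTTT", "CAGTTT"],
    )


@pytest.fixture
def square_sites() -> dict[str, tuple[float, float]]:
    return {"s1": (0.0, 0.0), "s2": (1.0, 0.0), "s3": (0.0, 1.0), "s4": (1.0, 1.0)}


@pytest.fixture
def sample_table() -> SampleTable:
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ["a", "b", "c", "d"],
                "site_id": ["s1", "s1", "s2", "s2"],
                "lat": [45.0, 45.0, 47.0, 47.0],
                "lon": [7.0, 7.0, 9.0, 9.0],
                "geo_group": ["west", "west", "east", "east"],
                "colour_label": ["red", "red", "dark", "dark"],
            }
        )
    )


@pytest.fixture
def chem_matrix() -> ChemProfileMatrix:
    return ChemProfileMatrix(
        pd.DataFrame(
            [[60.0, 30.0, 10.0], [50.0, 25.0, 25.0]],
            index=["a", "b"],
            columns=["c1", "c2", "c3"],
        )
    )


def small_sim_config(**overrides) -> SimulationConfig:
    """Down-scaled study conditions used across the stochastic tests."""
    defaults = dict(
        n_sites=12,
        n_individuals=60,
        loci=[
            LocusConfig("locusA", 400, 6, 0.6),
            LocusConfig("locusB", 300, 4, 0.5),
        ],
        n_geo_groups=5,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def small_dataset():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(small_sim_config(), seed=11)


def rng_seeds(n: int, base: int = 1234) -> list[int]:
    return list(np.random.default_rng(base).integers(0, 2**31 - 1, n))
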