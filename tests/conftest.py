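import numpy as np
import pandas as pd
import pytest

import spectrocal as sc


@pytest.fixture(scope="session")
def table() -> sc.ConcentrationTable:
    """The packaged 14-component x 10-sample reference concentration table."""
    return sc.load_concentration_table()


@pytest.fixture(scope="session")
def library() -> sc.ComponentLibrary:
    return sc.default_library(seed=0)


@pytest.fixture(scope="session")
def noiseless_study(library, table) -> sc.SpectraSet:
    """Deterministic noise-free study: 10 samples x 3 replicates."""
    return sc.generate_study(library, table, sc.NoiseModel.noiseless(seed=3))


@pytest.fixture(scope="session")
def noisy_study(library, table) -> sc.SpectraSet:
    return sc.generate_study(library, table, sc.NoiseModel(seed=7))


def make_table(values: dict[int, list], samples: list[str], names=None) -> sc.ConcentrationTable:
    """Small in-memory concentration table for targeted tests."""
    df = pd.DataFrame(values, index=samples).T
    df.index.name = "component_index"
    names = names or {i: f"component-{i}" for i in values}
    return sc.ConcentrationTable(values=df, sd=df * np.nan, component_names=names)


@pytest.fixture
def two_component_table() -> sc.ConcentrationTable:
    vals = {
        1: [0.2, 1.1, 0.5, 2.0, 0.8, 1.6],
        2: [1.5, 0.3, 0.9, 0.4, 2.2, 1.0],
    }
    return make_table(vals, list("ABCDEF"))
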