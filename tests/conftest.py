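import numpy as np
import pandas as pd
import pytest

from thmix import analysis as A
from thmix import generate as G


@pytest.fixture(scope="session")
def config():
    return G.default_config()


@pytest.fixture(scope="session")
def iso_sample(config):
    return G.generate_sample(G.Condition(0.0, 0.0), config, 20000, 101,
                             sample_kind="isotype")


@pytest.fixture(scope="session")
def th1_sample(config):
    return G.generate_sample(G.TH1, config, 20000, 102)


@pytest.fixture(scope="session")
def th2_sample(config):
    return G.generate_sample(G.TH2, config, 20000, 103)


@pytest.fixture(scope="session")
def mixed_sample(config):
    return G.generate_sample(G.MIXED, config, 20000, 104)


@pytest.fixture(scope="session")
def thresholds(iso_sample):
    return {c: A.isotype_threshold(iso_sample.cells[c]) for c in ("ifng", "il4")}


@pytest.fixture(scope="session")
def small_dataset(config):
    """4x4 grid at 4000 cells/sample: big enough for stable medians."""
    grid = [0.0, 4.0, 60.0, 540.0]
    return G.generate_matrix_dataset(config, grid, grid, 4000, 105)


@pytest.fixture(scope="session")
def mixed_state_table(mixed_sample):
    """Cell table with TF levels plus true binary cytokine states."""
    return pd.concat(
        [mixed_sample.cells[["tbet", "gata3"]].reset_index(drop=True),
         mixed_sample.states[["ifng_on", "il4_on"]].reset_index(drop=True)],
        axis=1)
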