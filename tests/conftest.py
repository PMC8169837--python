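import numpy as np
import pandas as pd
import pytest

from gliotraj.iokit import CountMatrix, ModuleLibrary
from gliotraj.synthdata import SimulationDesign, simulate_timeseries_counts


@pytest.fixture(scope="session")
def small_design() -> SimulationDesign:
    """Desk-scale design reused across tests: 300 cells/stage, default structure."""
    return SimulationDesign(n_cells_per_stage=300, seed=11)


@pytest.fixture(scope="session")
def small_timeseries(small_design):
    counts, meta, library = simulate_timeseries_counts(small_design)
    return counts, meta, library


@pytest.fixture()
def tiny_counts() -> CountMatrix:
    """3 genes x 2 units with known column sums (3, 7)."""
    return CountMatrix(
        values=np.array([[1, 0], [2, 3], [0, 4]]),
        gene_ids=["g1", "g2", "g3"],
        unit_ids=["u1", "u2"],
    )


@pytest.fixture()
def two_set_library() -> ModuleLibrary:
    return ModuleLibrary(sets={"S1": ["A", "B"], "S2": ["C", "D"]})
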