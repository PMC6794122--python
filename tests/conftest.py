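import numpy as np
import pandas as pd
import pytest

from cghpan import (
    PresenceAbsenceMatrix,
    ProbeSignalMatrix,
    SimulationConfig,
    simulate_collection,
)


def small_config(**overrides) -> SimulationConfig:
    """A 12-strain, 400-gene collection small enough for fast tests."""
    defaults = dict(
        n_strains=12,
        clade_sizes=(4, 4, 2, 2),
        n_genes=400,
        n_core_genes=250,
        probes_per_gene=3,
        n_control_probes=40,
        island_specs=((50, 15, 0, -0.05), (200, 20, 1, -0.05)),
        seed=11,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_collection():
    return simulate_collection(small_config())


@pytest.fixture
def tiny_probe_matrix():
    """3 gene probes + 2 controls across 2 strains, hand-computable."""
    values = pd.DataFrame(
        {
            "s1": [1000.0, 100.0, 400.0, 150.0, 150.0],
            "s2": [500.0, 700.0, 900.0, 100.0, 300.0],
        },
        index=["p1", "p2", "p3", "c1", "c2"],
    )
    probe_to_gene = pd.Series({"p1": "gA", "p2": "gA", "p3": "gB"})
    return ProbeSignalMatrix(values, probe_to_gene, frozenset({"c1", "c2"}))


def pa_from_array(arr, genes=None, strains=None) -> PresenceAbsenceMatrix:
    arr = np.asarray(arr, dtype=bool)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    strains = strains or [f"s{j}" for j in range(arr.shape[1])]
    return PresenceAbsenceMatrix(pd.DataFrame(arr, index=genes, columns=strains))
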