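import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from sipflow.activity import CountTable
from sipflow.simulate import SimulationConfig, default_community, simulate_dataset


def make_table(counts: dict[str, list[int]], taxa: list[str], lineages=None) -> CountTable:
    frame = pd.DataFrame(counts, index=taxa)
    return CountTable(frame, lineages)


@pytest.fixture(scope="session")
def labeled_dataset():
    """One simulated paired SIP experiment with three truly labeled taxa."""
    taxa = default_community(n_taxa=30, n_labeled=3, atom_excess=0.75, seed=11)
    return simulate_dataset(SimulationConfig(taxa=taxa, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
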