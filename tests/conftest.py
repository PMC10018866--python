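import numpy as np
import pytest
from hypothesis import settings

from nomehic import bsreads, simulate

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated bisulfite Hi-C dataset with local-control pairs."""
    cfg = simulate.SimulationConfig(
        seed=7,
        genome_length=300_000,
        n_anchor_pairs=5,
        n_pairs_per_anchor=40,
        n_local_pairs_per_anchor=20,
    )
    return simulate.simulate_linked_readpairs(cfg)


@pytest.fixture(scope="session")
def small_pairs(small_dataset):
    stats = {}
    pairs = bsreads.load_linked_pairs(
        small_dataset.reads, small_dataset.index, stats=stats
    )
    return pairs, stats
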