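import numpy as np
import pytest

from polystate import GeneModel, ProbeTrack, SimConfig, simulate_dataset


def make_track(starts, scores, chrom="chr2L", tile_width=35):
    return ProbeTrack({chrom: (np.asarray(starts), np.asarray(scores, dtype=float))},
                      tile_width=tile_width)


@pytest.fixture
def track_factory():
    return make_track


@pytest.fixture
def plus_gene():
    return GeneModel("gA", "chr2L", "+", 1000, 5000)


@pytest.fixture
def minus_gene():
    return GeneModel("gB", "chr2L", "-", 1000, 5000)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic dataset shared by state/pipeline tests."""
    return simulate_dataset(SimConfig(seed=42, n_genes=120))
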