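import numpy as np
import pytest

from breedsv.alignment import anchor_align
from breedsv.simulate import (COMPARATOR_BREED, FOCAL_BREED, SimulationConfig,
                              simulate_dataset)
from breedsv.svcalls import call_svs


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions: 2 x 300-kb chromosomes, one planted
    rearrangement, resolution scaled with the genome."""
    return SimulationConfig(
        n_chromosomes=2, chrom_length=300_000,
        n_shared_svs=10, n_private_svs=30,
        n_rearrangements=1, rearrangement_length_range=(60_000, 80_000),
        synteny_resolution=50_000, n_genes=30, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def focal_blocks(small_dataset):
    return anchor_align(small_dataset.assemblies[FOCAL_BREED],
                        small_dataset.reference, comparison="focal_vs_ref")


@pytest.fixture(scope="session")
def focal_calls(small_dataset, focal_blocks):
    return call_svs(focal_blocks, small_dataset.reference,
                    small_dataset.assemblies[FOCAL_BREED],
                    min_len=small_dataset.config.min_sv_length,
                    source_breed=FOCAL_BREED)


@pytest.fixture(scope="session")
def comparator_calls(small_dataset):
    blocks = anchor_align(small_dataset.assemblies[COMPARATOR_BREED],
                          small_dataset.reference, comparison="comp_vs_ref")
    return call_svs(blocks, small_dataset.reference,
                    small_dataset.assemblies[COMPARATOR_BREED],
                    min_len=small_dataset.config.min_sv_length,
                    source_breed=COMPARATOR_BREED)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
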