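import numpy as np
import pytest

from reflank.config import (DEFAULT_ENZYMES, PipelineConfig, SimConfig,
                            SomaticEventSpec)
from reflank.mapping import GenomeIndex
from reflank.simulate import build_mini_genome, make_l1_reference


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    """Compact mini-genome: fast to build, still carries every event class."""
    return PipelineConfig(sim=SimConfig(seed=42, genome_length=40_000,
                                        n_reference_res_per_family=3,
                                        n_cells=40, depth=6_000))


@pytest.fixture(scope="session")
def small_genome(small_config):
    return build_mini_genome(small_config.sim)


@pytest.fixture(scope="session")
def small_index(small_genome):
    return GenomeIndex(small_genome)


@pytest.fixture(scope="session")
def somatic_config() -> PipelineConfig:
    return PipelineConfig(sim=SimConfig(
        seed=7, genome_length=40_000, n_reference_res_per_family=3,
        n_cells=60, depth=9_000, tumor_blast_fraction=1.0,
        somatic_events=[SomaticEventSpec("L1HS", 0.5)]))


@pytest.fixture(scope="session")
def enzymes():
    return list(DEFAULT_ENZYMES.values())


@pytest.fixture(scope="session")
def l1_reference():
    return make_l1_reference(seed=3, n_l1hs=6, n_l1pa2=4, length=900,
                             n_decoys=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
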