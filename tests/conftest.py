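import pytest
from hypothesis import HealthCheck, settings

from tnscreen import simlib, tagproc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_config() -> simlib.SimConfig:
    """Small, fast screen: 8 genes of 300 bp, one essential."""
    return simlib.SimConfig(
        n_genes=8,
        gene_length_bp=300,
        intergenic_length_bp=100,
        essential_fraction=0.125,
        depth_per_sample=20_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_genome(tiny_config) -> simlib.GenomeAnnotation:
    return simlib.simulate_genome(tiny_config)


@pytest.fixture(scope="session")
def tiny_library(tiny_genome, tiny_config) -> simlib.MutantLibrary:
    return simlib.simulate_library(tiny_genome, tiny_config)


@pytest.fixture(scope="session")
def tiny_index(tiny_genome) -> tagproc.GenomeIndex:
    return tagproc.GenomeIndex(tiny_genome.sequence)


@pytest.fixture(scope="session")
def tiny_tag_spec(tiny_config) -> tagproc.TagSpec:
    return tagproc.TagSpec(tiny_config.tag_sequence)
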