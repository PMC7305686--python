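import warnings

import pytest

import ploidycomp as pc

# the generators legitimately warn when pseudogene offsets push CpG above 1;
# keep test output readable
warnings.filterwarnings("ignore", message=".*pseudogene offset.*")


@pytest.fixture(scope="session")
def cfg_small():
    return pc.GeneratorConfig(seed=11, n_genes=40)


@pytest.fixture(scope="session")
def small_genomes(cfg_small):
    """(diploid genes, hexaploid genes, pair table) at desk scale."""
    return pc.synth.generate_gene_models(cfg_small)


@pytest.fixture(scope="session")
def small_expression(cfg_small, small_genomes):
    _, _, pairs = small_genomes
    return pc.synth.generate_expression(cfg_small, pairs)
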