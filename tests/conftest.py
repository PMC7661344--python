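import pytest

from chipglyco import RegionIndex, gen_gene_models


@pytest.fixture(scope="session")
def chrom_lengths():
    return {f"chr{i}": 1_000_000 for i in range(1, 4)}


@pytest.fixture(scope="session")
def genes(chrom_lengths):
    return gen_gene_models(40, chrom_lengths, min_gap=4000, seed=11)


@pytest.fixture(scope="session")
def region_index(genes, chrom_lengths):
    return RegionIndex(genes, chrom_lengths)
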