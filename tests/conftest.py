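import pytest

from g4enrich.synthetic import SyntheticConfig, generate, generate_dataset

# small but fully featured dataset: two chromosomes, both strands, decoys,
# planted 3-fold enrichment in DE promoters/bodies
SMALL = dict(
    seed=42,
    n_chroms=2,
    chrom_length=4_000_000,
    n_genes=240,
    de_fraction=0.2,
    decoy_lambda=0.05,
)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(**SMALL)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_files(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("simdata")
    return generate(small_config, outdir)
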