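import pytest
from hypothesis import HealthCheck, settings

from tfcensus.catalog import write_catalog_tsv
from tfcensus.formats_io import GeneRecord
from tfcensus.synthetic_data import (
    GeneratorConfig,
    generate_catalog,
    generate_collection,
    write_collection,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def gene(gene_id, start, end, strand, replicon="chr1", genome="G", protein=None):
    """Shorthand GeneRecord constructor for layout-heavy tests."""
    return GeneRecord(
        gene_id=gene_id,
        protein_id=protein or gene_id,
        replicon_id=replicon,
        start=start,
        end=end,
        strand=strand,
        genome_id=genome,
    )


@pytest.fixture(scope="session")
def small_collection():
    """A small but fully featured synthetic collection with ground truth."""
    config = GeneratorConfig(seed=101, n_genomes=8, orf_range=(200, 900))
    bundles, truth = generate_collection(config)
    return config, bundles, truth


@pytest.fixture(scope="session")
def bundle_dir(small_collection, tmp_path_factory):
    """The small collection written to disk in the pipeline's input layout."""
    _, bundles, truth = small_collection
    path = tmp_path_factory.mktemp("bundle")
    write_collection(bundles, truth, path, generate_catalog(n=120, seed=101))
    return path
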