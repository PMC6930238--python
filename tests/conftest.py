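import numpy as np
import pytest
from hypothesis import settings

from trypcat.catalog import default_catalog
from trypcat.evidence import Thresholds
from trypcat.genome_io import GeneRecord, GenomeRecord
from trypcat.predict import build_call_matrix
from trypcat.simulate import CollectionDesign, build_collection

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture
def thresholds():
    return Thresholds()


def build_toy_genome(n_genes=15, contig="c1", strands=None, genome_id="G1",
                     **kwargs):
    """A bare genome with evenly spaced genes g000..g; proteins p000..p."""
    strands = strands or ["+"] * n_genes
    genes = [GeneRecord(f"g{k:03d}", f"p{k:03d}", contig, 100 + 1000 * k,
                        900 + 1000 * k, strands[k], rank_on_contig=k)
             for k in range(n_genes)]
    return GenomeRecord(genome_id, genes=genes, **kwargs)


@pytest.fixture
def toy_genome_factory():
    return build_toy_genome


@pytest.fixture(scope="session")
def planted_collection(catalog):
    """Seeded 40-strain collection with its ground truth (shared, read-only)."""
    collection, truth = build_collection(CollectionDesign(seed=7), catalog)
    return collection, truth


@pytest.fixture(scope="session")
def planted_matrix(planted_collection, catalog):
    collection, _ = planted_collection
    return build_call_matrix(collection, catalog)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
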