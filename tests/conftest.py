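import io

import numpy as np
import pytest

import geonorm as gn
from geonorm.synthetic_data import gene_info_text, simulate_corpus

MINIMAL_SOFT = """\
^DATASET = GDS100
!dataset_title = minimal fixture
!dataset_sample_organism = Homo sapiens
!dataset_type = gene expression
!dataset_channel_count = 1
!dataset_value_type = count
!dataset_platform = GPL100
!dataset_table_begin
ID_REF\tIDENTIFIER\tGSM1\tGSM2
P1\tTP53\t1\t2
P2\tEGFR\t3\t4
!dataset_table_end
"""

GENE_INFO = """\
#tax_id\tGeneID\tSymbol\tLocusTag\tSynonyms\tdbXrefs\tchromosome\tmap_location\tdescription\ttype_of_gene
9606\t7157\tTP53\t-\tP53|LFS1\t-\t17\t17p13.1\ttumor protein p53\tprotein-coding
9606\t1956\tEGFR\t-\tERBB|HER1\t-\t7\t7p11.2\tEGF receptor\tprotein-coding
9606\t672\tBRCA1\t-\t-\t-\t17\t17q21.31\tBRCA1 DNA repair\tprotein-coding
"""


@pytest.fixture
def minimal_dataset():
    return gn.parse_soft(io.StringIO(MINIMAL_SOFT))


@pytest.fixture
def small_catalog():
    return gn.load_gene_info(io.StringIO(GENE_INFO))


def build_matrices(spec):
    """Run a synthetic corpus through assembly, scaling and normalization."""
    datasets, annotations = simulate_corpus(spec)
    catalog = gn.load_gene_info(io.StringIO(gene_info_text(spec)))
    grids = [
        gn.aggregate_to_genes(ds, gn.map_probes(ds, catalog)) for ds in datasets
    ]
    raw = gn.assemble_matrix(grids)
    scaled, _ = gn.scale_matrix(raw)
    normalized, reference = gn.quantile_normalize(scaled)
    return raw, scaled, normalized, reference, annotations


@pytest.fixture
def corpus_builder():
    return build_matrices


def make_matrix(values, state="raw", gene_ids=None):
    """Small helper to wrap a plain array as an ExpressionMatrix."""
    values = np.asarray(values, dtype=float)
    n_genes, n_exps = values.shape
    if gene_ids is None:
        gene_ids = np.arange(1, n_genes + 1)
    return gn.ExpressionMatrix(
        gene_ids=gene_ids,
        experiment_ids=[f"E{j}" for j in range(n_exps)],
        values=values,
        state=state,
    )
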