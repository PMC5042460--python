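import numpy as np
import pandas as pd
import pytest

from lncconsensus import ExpressionMatrix, SimulationConfig


def make_matrix(values, gene_ids=None, sample_ids=None, subtype=None, batch=None):
    """Build an ExpressionMatrix from a raw array with placeholder metadata."""
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"G{i:03d}" for i in range(values.shape[0])]
    if sample_ids is None:
        sample_ids = [f"S{j:03d}" for j in range(values.shape[1])]
    meta = pd.DataFrame(
        {
            "cohort": "c1",
            "subtype": subtype if subtype is not None else "NA",
            "hormone_status": "NA",
            "batch": batch if batch is not None else "b1",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids), meta)


@pytest.fixture
def tiny_matrix():
    return make_matrix([[1.0, 2.0], [3.0, 4.0], [0.0, 5.0]])


@pytest.fixture(scope="session")
def default_cfg():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_cfg):
    from lncconsensus import simulate_cohort

    return simulate_cohort(default_cfg, "A")


@pytest.fixture(scope="session")
def annotation_frame():
    """Small hand-built annotation covering both biotypes."""
    rows = [
        # gene_id, symbol, chrom, start, end, strand, biotype, max_len
        ("PCA", "PCA", "chr1", 150, 300, "+", "protein_coding", 900),
        ("PCB", "PCB", "chr1", 10_000, 12_000, "+", "protein_coding", 1500),
        ("LNC_OK", "LNC_OK", "chr1", 5_000, 5_500, "+", "lincRNA", 500),
        ("LNC_SHORT", "LNC_SHORT", "chr1", 6_000, 6_399, "+", "lincRNA", 399),
        ("LNC_OVL", "LNC_OVL", "chr1", 100, 200, "+", "lincRNA", 600),
        ("LNC_ABUT", "LNC_ABUT", "chr1", 300, 400, "-", "lincRNA", 800),
    ]
    ann = pd.DataFrame(
        rows,
        columns=["gene_id", "symbol", "chrom", "start", "end", "strand",
                 "biotype", "max_transcript_len"],
    ).set_index("gene_id", drop=False)
    ann.index.name = None
    return ann
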