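"""Shared fixtures: small synthetic cohorts reused across test modules.

Session scope amortizes generation and scoring cost; tests must not
mutate fixture objects.
"""

import warnings

import numpy as np
import pandas as pd
import pytest

from triaxis import enrichment, synthetic
from triaxis.containers import ExpressionMatrix, GeneSet, GeneSetCollection

TISSUE = ["LE", "IT", "CT", "PAN", "MVP"]


@pytest.fixture(scope="session")
def cohort_protein():
    m, truth = synthetic.generate_regional_cohort(8, 1000, seed=42, modality="protein")
    return m, truth


@pytest.fixture(scope="session")
def cohort_rna():
    m, truth = synthetic.generate_regional_cohort(8, 1000, seed=42, modality="rna_tpm")
    return m, truth


@pytest.fixture(scope="session")
def genesets(cohort_rna):
    _, truth = cohort_rna
    return synthetic.generate_geneset_collection(truth, n_decoys=10, seed=42)


@pytest.fixture(scope="session")
def tissue_scores(cohort_rna, genesets):
    m, _ = cohort_rna
    tissue = m.subset_niches(TISSUE)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return enrichment.ssgsea_scores(tissue, genesets)


@pytest.fixture()
def tiny_matrix():
    """4 genes x 3 samples with hand-checkable values."""
    values = pd.DataFrame(
        {"s1": [4.0, 3.0, 2.0, 1.0], "s2": [1.0, 2.0, 3.0, 4.0], "s3": [4.0, 3.0, 2.0, 1.0]},
        index=["g1", "g2", "g3", "g4"],
    )
    meta = pd.DataFrame(
        {"patient_id": ["p1", "p1", "p2"], "niche": ["CT", "CT", "PAN"], "modality": "rna_tpm"},
        index=values.columns,
    )
    return ExpressionMatrix(values, meta, "rna_tpm")


def make_expression(values: dict, niches=None, modality="rna_tpm", index=None):
    """Build a small ExpressionMatrix from a column dict."""
    df = pd.DataFrame(values, index=index, dtype=float)
    niches = niches or ["CT"] * df.shape[1]
    meta = pd.DataFrame(
        {"patient_id": [f"p{i}" for i in range(df.shape[1])], "niche": niches, "modality": modality},
        index=df.columns,
    )
    mask = df == 0 if modality == "protein" else None
    return ExpressionMatrix(df, meta, modality, missing_mask=mask)
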