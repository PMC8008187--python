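"""Shared fixtures: small synthetic datasets and hand-built matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from modlink import io as mio
from modlink import simulate
from modlink.containers import ExpressionMatrix


def make_em(values: np.ndarray, gene_ids=None, sample_ids=None,
            scale="log2norm", tissue="islet", weeks=None, diets=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix with minimal consistent metadata."""
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    weeks = weeks if weeks is not None else [4] * n_samples
    diets = diets if diets is not None else ["HFD"] * n_samples
    meta = pd.DataFrame(
        {
            "subject_id": [f"sub{i}" for i in range(n_samples)],
            "tissue": tissue,
            "week": weeks,
            "diet": diets,
            "replicate": list(range(1, n_samples + 1)),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    vals = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(vals, meta, scale=scale)


@pytest.fixture(scope="session")
def demo_data():
    """Small planted dataset shared by read-only tests."""
    cfg = simulate.demo_config(seed=7)
    return simulate.generate_dataset(cfg)


@pytest.fixture(scope="session")
def demo_logged(demo_data):
    islet, liver, traits, truth = demo_data
    isl_log = mio.normalize_counts(mio.filter_genes(islet))
    liv_log = mio.normalize_counts(mio.filter_genes(liver))
    design = mio.align_paired_samples(isl_log, liv_log)
    return isl_log, liv_log, traits, truth, design
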