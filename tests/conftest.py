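"""Shared fixtures: small hand-built datasets and builders."""

from __future__ import annotations

import pandas as pd
import pytest

from orthoquant.calls import ExpressionCallSet
from orthoquant.io import ExpressionDataset
from orthoquant.orthology import OrthologyMap


def make_dataset(dataset_id, data, species="human", replicates=None,
                 gene_types=None):
    """Build an ExpressionDataset from {gene: [tpm per replicate]}."""
    n_reps = len(next(iter(data.values())))
    if replicates is None:
        replicates = [f"r{i + 1}" for i in range(n_reps)]
    tpm = pd.DataFrame.from_dict(data, orient="index", columns=replicates)
    tpm.index.name = "gene_id"
    return ExpressionDataset(dataset_id=dataset_id, species=species, tpm=tpm,
                             gene_types=gene_types)


def make_calls(dataset_id, summary_tpm, highly=()):
    """Build an ExpressionCallSet directly from {gene: mean TPM}."""
    series = pd.Series(summary_tpm, dtype=float)
    return ExpressionCallSet(
        dataset_id=dataset_id,
        expressed=frozenset(series.index),
        highly_expressed=frozenset(highly),
        summary_tpm=series,
    )


@pytest.fixture
def toy_dataset():
    return make_dataset("TOY", {
        "g1": [1.2, 3.0, 1.1],
        "g2": [1.2, 1.0, 5.0],
        "g3": [0.0, 0.0, 0.0],
        "g4": [10.0, 12.0, 11.0],
    })


@pytest.fixture
def toy_orthology():
    return OrthologyMap(
        species_a="human", species_b="zebrafish",
        pairs=(("a1", "b1", 1), ("a1", "b2", 1), ("a2", "b2", 0)),
    )
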