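"""Expression-status calls and TPM-distribution summaries.

Two gene statuses are defined per dataset:

* *expressed* — TPM strictly greater than a threshold (default 1) in **every**
  replicate;
* *highly expressed* — among the expressed genes, per-replicate z-scores of
  log TPM exceed a threshold (default 1.5) in at least ``min_replicates``
  replicates (default: 2 of 3, generalised to ``ceil(2/3 * n)``).

Z-scores are computed column-wise (within a replicate) over the expressed
genes only, so no pseudocount is needed for the log; the log base cancels in
the z-score and is exposed only for the logged values themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionDataset

__all__ = [
    "ExpressionCallSet",
    "TpmDistribution",
    "call_expressed",
    "call_highly_expressed",
    "make_call_set",
    "tpm_distribution",
    "zero_fraction",
    "fraction_below",
]

DEFAULT_TPM_THRESHOLD = 1.0
DEFAULT_Z_THRESHOLD = 1.5


@dataclass
class ExpressionCallSet:
    """Expression calls for one dataset.

    ``summary_tpm`` holds the mean TPM across replicates for the expressed
    genes and is the ranking signal used downstream for quantile assignment.
    """

    dataset_id: str
    expressed: frozenset[str]
    highly_expressed: frozenset[str]
    summary_tpm: pd.Series

    def __post_init__(self) -> None:
        if not self.highly_expressed <= self.expressed:
            raise ValidationError(
                f"{self.dataset_id!r}: highly_expressed must be a subset of expressed"
            )
        if set(self.summary_tpm.index) != set(self.expressed):
            raise ValidationError(
                f"{self.dataset_id!r}: summary_tpm must cover exactly the expressed genes"
            )


@dataclass
class TpmDistribution:
    """Per-replicate gene counts over TPM intervals, optionally by biotype."""

    dataset_id: str
    bin_labels: tuple[str, ...]
    counts: pd.DataFrame  # bins x replicates
    by_type: dict[str, pd.DataFrame] | None = None


def call_expressed(ds: ExpressionDataset, tpm_threshold: float = DEFAULT_TPM_THRESHOLD) -> frozenset[str]:
    """Genes with TPM strictly above ``tpm_threshold`` in all replicates."""
    mask = (ds.tpm > tpm_threshold).all(axis=1)
    return frozenset(ds.tpm.index[mask])


def default_min_replicates(n_replicates: int) -> int:
    """2-of-3 rule generalised: ``ceil(2/3 * n)``."""
    return math.ceil(2 * n_replicates / 3)


def call_highly_expressed(
    ds: ExpressionDataset,
    expressed: frozenset[str] | set[str],
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    min_replicates: int | None = None,
    ddof: int = 1,
    log_base: float = 2.0,
) -> frozenset[str]:
    """Genes whose per-replicate log-TPM z-score (over expressed genes)
    exceeds ``z_threshold`` in at least ``min_replicates`` replicates.

    ``ddof=1`` uses the sample standard deviation; ``ddof=0`` the population
    one.  Raises :class:`ValidationError` on a zero-SD (degenerate) replicate.
    """
    genes = sorted(expressed)
    unknown = set(genes) - set(ds.tpm.index)
    if unknown:
        raise ValidationError(
            f"{ds.dataset_id!r}: expressed gene {sorted(unknown)[0]!r} not in dataset"
        )
    if len(genes) < 2:
        raise ValidationError(f"{ds.dataset_id!r}: need >=2 expressed genes for z-scores")
    sub = ds.tpm.loc[genes]
    if (sub.to_numpy() <= 0).any():
        raise ValidationError(
            f"{ds.dataset_id!r}: expressed genes must have positive TPM for the log"
        )
    log_tpm = np.log(sub.to_numpy()) / np.log(log_base)
    mean = log_tpm.mean(axis=0)
    sd = log_tpm.std(axis=0, ddof=ddof)
    if (sd == 0).any():
        rep = sub.columns[int(np.argwhere(sd == 0)[0][0])]
        raise ValidationError(
            f"{ds.dataset_id!r}: zero log-TPM standard deviation in replicate {rep!r}"
        )
    z = (log_tpm - mean) / sd
    if min_replicates is None:
        min_replicates = default_min_replicates(ds.n_replicates)
    n_exceed = (z > z_threshold).sum(axis=1)
    return frozenset(np.asarray(genes, dtype=object)[n_exceed >= min_replicates])


def make_call_set(
    ds: ExpressionDataset,
    tpm_threshold: float = DEFAULT_TPM_THRESHOLD,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    min_replicates: int | None = None,
    ddof: int = 1,
) -> ExpressionCallSet:
    """Run both calls on a dataset and bundle the result."""
    expressed = call_expressed(ds, tpm_threshold)
    if len(expressed) >= 2:
        high = call_highly_expressed(
            ds, expressed, z_threshold=z_threshold,
            min_replicates=min_replicates, ddof=ddof,
        )
    else:
        high = frozenset()
    summary = ds.tpm.loc[sorted(expressed)].mean(axis=1)
    return ExpressionCallSet(
        dataset_id=ds.dataset_id,
        expressed=expressed,
        highly_expressed=high,
        summary_tpm=summary,
    )


def tpm_distribution(
    ds: ExpressionDataset,
    bin_edges: tuple[float, ...] = (1.0, 10.0, 100.0),
) -> TpmDistribution:
    """Count genes per TPM interval per replicate.

    The intervals are ``{0}``, ``(0, e1)``, ``[e1, e2)``, ..., ``[e_last, inf)``;
    the default edges ``(1, 10, 100)`` give the five-interval scheme
    ``{0}, (0,1), [1,10), [10,100), [100,inf)``.  Counts conserve the total
    gene number in every replicate.
    """
    edges = tuple(float(e) for e in bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])) or (edges and edges[0] <= 0):
        raise ValidationError("bin_edges must be strictly increasing and positive")
    labels = ["0", f"(0,{_fmt(edges[0])})"] if edges else ["0", "(0,inf)"]
    for a, b in zip(edges, edges[1:]):
        labels.append(f"[{_fmt(a)},{_fmt(b)})")
    if edges:
        labels.append(f"[{_fmt(edges[-1])},inf)")

    def _count(frame: pd.DataFrame) -> pd.DataFrame:
        vals = frame.to_numpy()
        out = np.empty((len(labels), vals.shape[1]), dtype=int)
        out[0] = (vals == 0).sum(axis=0)
        full_edges = (0.0, *edges, np.inf)
        for i, (lo, hi) in enumerate(zip(full_edges, full_edges[1:]), start=1):
            out[i] = ((vals > lo if lo == 0.0 else vals >= lo) & (vals < hi)).sum(axis=0)
        return pd.DataFrame(out, index=labels, columns=frame.columns)

    counts = _count(ds.tpm)
    by_type = None
    if ds.gene_types:
        by_type = {}
        types = pd.Series(ds.gene_types)
        for biotype in sorted(set(types.values)):
            members = types.index[types == biotype]
            by_type[biotype] = _count(ds.tpm.loc[ds.tpm.index.intersection(members)])
    return TpmDistribution(
        dataset_id=ds.dataset_id,
        bin_labels=tuple(labels),
        counts=counts,
        by_type=by_type,
    )


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


def zero_fraction(ds: ExpressionDataset) -> pd.Series:
    """Per-replicate fraction of genes with TPM exactly zero."""
    return (ds.tpm == 0).mean(axis=0)


def fraction_below(ds: ExpressionDataset, threshold: float = 1.0) -> pd.Series:
    """Per-replicate fraction of genes with TPM strictly below ``threshold``."""
    return (ds.tpm < threshold).mean(axis=0)
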