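"""Extraction and ranking of highly concordant orthologous genes.

A gene qualifies for one cross-species comparison when at least one of its
high-confidence expressed ortholog pairs falls in the top ``k x k`` quantile
block (top 30 % of expression in both species for ``k=3`` of 10).  Genes that
qualify in *every* query-side dataset form the highly concordant set, which
is ranked by grand-mean TPM over every replicate of every dataset: the gene's
own TPM in the datasets that carry it, and its qualifying orthologs' TPM
(averaged gene-level first) in the other species' datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calls import call_expressed
from .errors import ValidationError
from .io import ExpressionDataset, ReferenceGeneList
from .orthology import OrthologyMap, filter_high_confidence
from .quantile_map import QuantileMapping

__all__ = [
    "ConcordanceResult",
    "top_region_genes",
    "intersect_and_rank",
    "cross_reference",
    "overlap_percent",
]


def top_region_genes(qm: QuantileMapping, k: int = 3) -> frozenset[str]:
    """Unique row-dataset gene IDs of pairs in the top k x k quantile block."""
    if k < 1 or k > qm.n_quantiles:
        raise ValidationError(f"k must lie in 1..{qm.n_quantiles}, got {k}")
    if qm.members is None:
        raise ValidationError("mapping carries no member lists")
    out: set[str] = set()
    for (r, c), entries in qm.members.items():
        if r <= k and c <= k:
            out.update(p[0] for p in entries if p[0] is not None)
    return frozenset(out)


def overlap_percent(sets) -> float:
    """Intersection size as a percentage of the smallest set."""
    sets = [set(s) for s in sets]
    if any(not s for s in sets):
        raise ValidationError("overlap percentage undefined for an empty set")
    inter = set.intersection(*sets)
    return 100.0 * len(inter) / min(len(s) for s in sets)


@dataclass
class ConcordanceResult:
    """Concordant genes per comparison, their intersection, and the ranking."""

    per_dataset: dict[str, frozenset[str]]
    intersection: frozenset[str]
    overlap_pct: float
    ranking: list[tuple[str, float]]  # (gene, grand-mean TPM), descending
    multi_ortholog_genes: frozenset[str]  # genes pooled over >1 ortholog somewhere

    def top(self, n: int = 25) -> list[tuple[str, float]]:
        return self.ranking[:n]


def intersect_and_rank(
    sets: dict[str, frozenset[str] | set[str]],
    datasets: list[ExpressionDataset],
    orthology: OrthologyMap | None = None,
    query_side: str = "a",
    tpm_threshold: float = 1.0,
) -> ConcordanceResult:
    """Intersect per-comparison concordant sets and rank by grand-mean TPM.

    ``sets`` maps a query dataset ID to the gene set it contributed (all IDs
    in the query species).  For each intersection gene the grand mean pools
    one value per replicate of every dataset: the gene's own TPM where the
    gene is present, otherwise the mean TPM of its high-confidence orthologs
    that are expressed in that dataset (TPM > ``tpm_threshold`` in all
    replicates).  A gene with no expressed ortholog in some dataset raises —
    by construction this cannot happen for genes from top-region sets.
    """
    if not sets:
        raise ValidationError("need at least one concordant gene set")
    members = [frozenset(s) for s in sets.values()]
    intersection = frozenset(set.intersection(*map(set, members)))
    pct = 100.0 * len(intersection) / min(len(s) for s in members) if all(members) else 0.0

    hc = filter_high_confidence(orthology) if orthology is not None else None
    ortho_map = None
    if hc is not None:
        ortho_map = hc.a_to_b if query_side == "a" else hc.b_to_a

    expressed_cache = {
        ds.dataset_id: call_expressed(ds, tpm_threshold) for ds in datasets
    }

    multi: set[str] = set()
    ranking: list[tuple[str, float]] = []
    for gene in sorted(intersection):
        values: list[float] = []
        for ds in datasets:
            if gene in ds.tpm.index:
                values.extend(float(v) for v in ds.tpm.loc[gene])
                continue
            if ortho_map is None:
                raise ValidationError(
                    f"gene {gene!r} absent from dataset {ds.dataset_id!r} and no "
                    f"orthology map was supplied"
                )
            partners = sorted(
                p for p in ortho_map.get(gene, frozenset())
                if p in expressed_cache[ds.dataset_id]
            )
            if not partners:
                raise ValidationError(
                    f"gene {gene!r} has no expressed high-confidence ortholog in "
                    f"dataset {ds.dataset_id!r}"
                )
            if len(partners) > 1:
                multi.add(gene)
            block = ds.tpm.loc[partners].mean(axis=0)  # gene-level average first
            values.extend(float(v) for v in block)
        ranking.append((gene, float(np.mean(values))))
    ranking.sort(key=lambda t: (-t[1], t[0]))

    return ConcordanceResult(
        per_dataset={k: frozenset(v) for k, v in sets.items()},
        intersection=intersection,
        overlap_pct=pct,
        ranking=ranking,
        multi_ortholog_genes=frozenset(multi),
    )


def cross_reference(
    result: ConcordanceResult, ref: ReferenceGeneList
) -> list[tuple[str, float]]:
    """Ranking members present in a reference list, rank order preserved."""
    ref_set = ref.as_set()
    return [(g, t) for g, t in result.ranking if g in ref_set]
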