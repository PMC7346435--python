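"""Quantile assignment and the extended quantile-mapping matrix.

Expressed genes of each dataset are ranked by mean TPM and split into ``n``
contiguous quantiles (quantile 1 = top expression; sizes differ by at most
one, larger blocks first; TPM ties broken by gene ID).  Two datasets are then
cross-tabulated into an ``(n+2) x (n+2)`` matrix:

* cells ``(1..n, 1..n)`` — one count per high-confidence ortholog pair whose
  members are expressed in both datasets (cross-species mode) or per shared
  gene (same-species mode);
* row/column ``n+1`` — genes expressed on that side whose high-confidence
  orthologs are all unexpressed on the other side;
* row/column ``n+2`` — genes expressed on that side with no high-confidence
  ortholog at all (unused in same-species mode).

Region enrichment tests whether a rectangular block of quantile cells holds
more pairs than a uniform spread of the grid total would give, via Fisher's
exact test on the region-membership 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calls import ExpressionCallSet
from .errors import ValidationError
from .io import ReferenceGeneList
from .orthology import OrthologyMap, filter_high_confidence

__all__ = [
    "QuantileAssignment",
    "QuantileMapping",
    "RegionEnrichment",
    "assign_quantiles",
    "build_quantile_mapping",
    "region_enrichment",
    "uniform_expected",
    "project_reference_list",
    "summarize_projection",
]

Pair = tuple  # (row gene or None, col gene or None)


@dataclass
class QuantileAssignment:
    """Expressed genes of one dataset assigned to quantiles 1..n (1 = top)."""

    dataset_id: str
    n_quantiles: int
    quantile_of: dict[str, int]
    summary_tpm: pd.Series

    def genes_in(self, q: int) -> list[str]:
        return [g for g, qq in self.quantile_of.items() if qq == q]

    def sizes(self) -> list[int]:
        out = [0] * self.n_quantiles
        for q in self.quantile_of.values():
            out[q - 1] += 1
        return out


def assign_quantiles(calls: ExpressionCallSet, n_quantiles: int = 10) -> QuantileAssignment:
    """Split the expressed genes into ``n_quantiles`` expression deciles.

    Ranking is by summary TPM descending with ties broken by gene ID, so the
    assignment is deterministic.  When the gene count is not divisible by
    ``n_quantiles`` the earlier (higher-expression) quantiles take the extra
    genes.
    """
    genes = sorted(calls.expressed, key=lambda g: (-calls.summary_tpm[g], g))
    n = len(genes)
    if n < n_quantiles:
        raise ValidationError(
            f"{calls.dataset_id!r}: {n} expressed genes < {n_quantiles} quantiles"
        )
    base, extra = divmod(n, n_quantiles)
    quantile_of: dict[str, int] = {}
    pos = 0
    for q in range(1, n_quantiles + 1):
        size = base + (1 if q <= extra else 0)
        for g in genes[pos:pos + size]:
            quantile_of[g] = q
        pos += size
    return QuantileAssignment(
        dataset_id=calls.dataset_id,
        n_quantiles=n_quantiles,
        quantile_of=quantile_of,
        summary_tpm=calls.summary_tpm,
    )


@dataclass
class QuantileMapping:
    """The extended ``(n+2) x (n+2)`` cross-tabulation of two datasets.

    ``counts`` is indexed 0-based; ``members`` (1-based cell keys) lists the
    (row gene, col gene) entries per cell, with ``None`` on the side that has
    no partner.  ``members=None`` marks a counts-only mapping (e.g. one
    rebuilt from a file or simulated directly).
    """

    row_dataset: str
    col_dataset: str
    n_quantiles: int
    mode: str  # "cross-species" | "same-species"
    counts: np.ndarray
    members: dict[tuple[int, int], tuple[Pair, ...]] | None = None
    avg_tpm_row: dict[int, float] = field(default_factory=dict)
    avg_tpm_col: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.n_quantiles
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (n + 2, n + 2):
            raise ValidationError(
                f"counts must be ({n + 2}, {n + 2}), got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.members is not None:
            for (r, c), entries in self.members.items():
                if self.counts[r - 1, c - 1] != len(entries):
                    raise ValidationError(
                        f"cell ({r},{c}): count {self.counts[r - 1, c - 1]} != "
                        f"{len(entries)} member entries"
                    )
            if self.counts.sum() != sum(len(v) for v in self.members.values()):
                raise ValidationError("counts and members disagree in total")

    # -- accessors ----------------------------------------------------------
    def count(self, r: int, c: int) -> int:
        """Count at 1-based cell (r, c)."""
        return int(self.counts[r - 1, c - 1])

    @property
    def grid(self) -> np.ndarray:
        """The n x n quantile-cell block."""
        n = self.n_quantiles
        return self.counts[:n, :n]

    @property
    def n_grid_pairs(self) -> int:
        """Total pairs mapped into the quantile grid."""
        return int(self.grid.sum())

    def unique_genes(self, side: str = "row") -> dict[str, frozenset[str]]:
        """Unique gene IDs per category on one side.

        Categories: ``"grid"`` (expressed with an expressed high-confidence
        ortholog), ``"unexpressed_partner"`` and ``"no_ortholog"``.
        """
        if self.members is None:
            raise ValidationError("mapping carries no member lists")
        n = self.n_quantiles
        idx = 0 if side == "row" else 1
        grid: set[str] = set()
        unexp: set[str] = set()
        noorth: set[str] = set()
        for (r, c), entries in self.members.items():
            for pair in entries:
                g = pair[idx]
                if g is None:
                    continue
                extra = c if side == "row" else r
                if r <= n and c <= n:
                    grid.add(g)
                elif extra == n + 1:
                    unexp.add(g)
                elif extra == n + 2:
                    noorth.add(g)
        return {
            "grid": frozenset(grid),
            "unexpressed_partner": frozenset(unexp),
            "no_ortholog": frozenset(noorth),
        }


def build_quantile_mapping(
    qa_row: QuantileAssignment,
    qa_col: QuantileAssignment,
    om: OrthologyMap | None = None,
    row_side: str = "a",
) -> QuantileMapping:
    """Cross-tabulate two quantile assignments into a QuantileMapping.

    Cross-species mode (``om`` given): the counting unit in the grid is the
    high-confidence ortholog pair; a row-expressed gene whose high-confidence
    orthologs are all unexpressed in the column dataset goes to column
    ``n+1``; one with no high-confidence ortholog goes to column ``n+2``
    (symmetrically for the rows).  ``row_side`` says which side of the
    orthology map the row dataset's genes live on (``"a"`` or ``"b"``).

    Same-species mode (``om is None``): genes are matched by identity and
    genes unique to one dataset go to row/column ``n+1``.
    """
    if qa_row.n_quantiles != qa_col.n_quantiles:
        raise ValidationError("row and column assignments use different n_quantiles")
    n = qa_row.n_quantiles
    counts = np.zeros((n + 2, n + 2), dtype=int)
    members: dict[tuple[int, int], list[Pair]] = {}

    def add(r: int, c: int, pair: Pair) -> None:
        counts[r - 1, c - 1] += 1
        members.setdefault((r, c), []).append(pair)

    expressed_row = set(qa_row.quantile_of)
    expressed_col = set(qa_col.quantile_of)

    if om is None:
        mode = "same-species"
        for g in sorted(expressed_row):
            qr = qa_row.quantile_of[g]
            if g in expressed_col:
                add(qr, qa_col.quantile_of[g], (g, g))
            else:
                add(qr, n + 1, (g, None))
        for g in sorted(expressed_col - expressed_row):
            add(n + 1, qa_col.quantile_of[g], (None, g))
    else:
        mode = "cross-species"
        if row_side not in ("a", "b"):
            raise ValidationError(f"row_side must be 'a' or 'b', got {row_side!r}")
        hc = filter_high_confidence(om)
        if row_side == "a":
            row_orth, col_orth = hc.a_to_b, hc.b_to_a
            row_universe, col_universe = om.genes_a, om.genes_b
        else:
            row_orth, col_orth = hc.b_to_a, hc.a_to_b
            row_universe, col_universe = om.genes_b, om.genes_a
        if om.n_pairs:
            if not (expressed_row & row_universe) and (expressed_row & col_universe):
                other = "b" if row_side == "a" else "a"
                raise ValidationError(
                    f"row dataset {qa_row.dataset_id!r} genes match orthology side "
                    f"{other!r}; check row_side/species"
                )
        for g in sorted(expressed_row):
            qr = qa_row.quantile_of[g]
            partners = row_orth.get(g, frozenset())
            if not partners:
                add(qr, n + 2, (g, None))
                continue
            expressed_partners = sorted(partners & expressed_col)
            if not expressed_partners:
                add(qr, n + 1, (g, None))
                continue
            for p in expressed_partners:
                add(qr, qa_col.quantile_of[p], (g, p))
        for g in sorted(expressed_col):
            qc = qa_col.quantile_of[g]
            partners = col_orth.get(g, frozenset())
            if not partners:
                add(n + 2, qc, (None, g))
            elif not (partners & expressed_row):
                add(n + 1, qc, (None, g))

    def quantile_means(qa: QuantileAssignment) -> dict[int, float]:
        out: dict[int, float] = {}
        for q in range(1, n + 1):
            genes = qa.genes_in(q)
            out[q] = float(qa.summary_tpm[genes].mean()) if genes else float("nan")
        return out

    return QuantileMapping(
        row_dataset=qa_row.dataset_id,
        col_dataset=qa_col.dataset_id,
        n_quantiles=n,
        mode=mode,
        counts=counts,
        members={k: tuple(v) for k, v in members.items()},
        avg_tpm_row=quantile_means(qa_row),
        avg_tpm_col=quantile_means(qa_col),
    )


@dataclass
class RegionEnrichment:
    """Fisher's-exact enrichment of a rectangular block of quantile cells."""

    rows: tuple[int, ...]
    cols: tuple[int, ...]
    observed: int
    expected: float
    odds_ratio: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]


def uniform_expected(
    n_pairs: int, n_quantiles: int, n_row_cells: int = 1, n_col_cells: int = 1
) -> float:
    """Expected pairs in a block under a uniform spread over the n x n grid."""
    return n_pairs * n_row_cells * n_col_cells / n_quantiles ** 2


def region_enrichment(
    qm: QuantileMapping,
    rows,
    cols,
    alternative: str = "two-sided",
) -> RegionEnrichment:
    """Test a quantile-cell region for enrichment over a uniform spread.

    Over the N pairs in the n x n grid, builds the 2x2 table
    ``[[in-rows & in-cols, in-rows & not], [not & in-cols, neither]]`` and
    runs Fisher's exact test (``alternative`` as in scipy; use ``"greater"``
    for a pure over-representation test).  The reported expectation is the
    uniform one, ``N * |rows| * |cols| / n^2``.
    """
    n = qm.n_quantiles
    rows = tuple(sorted(set(int(r) for r in rows)))
    cols = tuple(sorted(set(int(c) for c in cols)))
    if not rows or not cols:
        raise ValidationError("region must contain at least one row and one column")
    if any(r < 1 or r > n for r in rows) or any(c < 1 or c > n for c in cols):
        raise ValidationError(f"region indices must lie in 1..{n} (quantile cells only)")
    grid = qm.grid
    total = int(grid.sum())
    if total == 0:
        raise ValidationError("no pairs mapped into the quantile grid")
    r_idx = np.asarray(rows) - 1
    c_idx = np.asarray(cols) - 1
    a = int(grid[np.ix_(r_idx, c_idx)].sum())
    row_tot = int(grid[r_idx, :].sum())
    col_tot = int(grid[:, c_idx].sum())
    table = ((a, row_tot - a), (col_tot - a, total - row_tot - col_tot + a))
    odds_ratio, p = stats.fisher_exact(np.asarray(table), alternative=alternative)
    return RegionEnrichment(
        rows=rows,
        cols=cols,
        observed=a,
        expected=uniform_expected(total, n, len(rows), len(cols)),
        odds_ratio=float(odds_ratio),
        p_value=float(p),
        table=table,
    )


def project_reference_list(qm: QuantileMapping, ref: ReferenceGeneList) -> QuantileMapping:
    """Restrict a mapping to entries whose row gene is in a reference list.

    Entries with no row gene (the column-side-only categories) are dropped.
    All structural invariants are preserved; use :func:`summarize_projection`
    for the per-category counts.
    """
    if qm.members is None:
        raise ValidationError("cannot project a counts-only mapping")
    ref_set = ref.as_set()
    n = qm.n_quantiles
    counts = np.zeros((n + 2, n + 2), dtype=int)
    members: dict[tuple[int, int], tuple[Pair, ...]] = {}
    for (r, c), entries in qm.members.items():
        kept = tuple(p for p in entries if p[0] is not None and p[0] in ref_set)
        if kept:
            members[(r, c)] = kept
            counts[r - 1, c - 1] = len(kept)
    return QuantileMapping(
        row_dataset=qm.row_dataset,
        col_dataset=qm.col_dataset,
        n_quantiles=n,
        mode=qm.mode,
        counts=counts,
        members=members,
        avg_tpm_row=dict(qm.avg_tpm_row),
        avg_tpm_col=dict(qm.avg_tpm_col),
    )


def summarize_projection(qm: QuantileMapping) -> dict[str, int]:
    """Unique row-gene counts per category of a (projected) mapping.

    Returns ``n_expressed`` (row genes anywhere), ``n_orthologous`` (grid or
    unexpressed-partner categories) and ``n_orthologous_expressed_col``
    (grid only).
    """
    cats = qm.unique_genes(side="row")
    grid = cats["grid"]
    orth = grid | cats["unexpressed_partner"]
    expressed = orth | cats["no_ortholog"]
    return {
        "n_expressed": len(expressed),
        "n_orthologous": len(orth),
        "n_orthologous_expressed_col": len(grid),
    }
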