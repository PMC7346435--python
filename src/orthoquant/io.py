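"""Tabular I/O for the pipeline: TPM matrices, GMT gene sets, reference gene
lists, and quantile-map exports.

All readers validate strictly and raise :class:`~orthoquant.errors.ParseError`
or :class:`~orthoquant.errors.ValidationError`; nothing is silently coerced.
Gene identifiers are opaque, case-sensitive strings.  Ensembl-style version
suffixes (``ENSG00000123456.7``) are kept unless ``strip_id_version=True`` is
requested explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "ExpressionDataset",
    "GeneSetCollection",
    "ReferenceGeneList",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "read_gene_list",
    "write_quantile_map",
    "read_quantile_map_counts",
]


@dataclass
class ExpressionDataset:
    """A gene x replicate TPM matrix for one dataset.

    Parameters
    ----------
    dataset_id
        Short label, e.g. ``"H1"``, ``"H2"``, ``"ZF"``.
    species
        Species label, e.g. ``"human"``.
    tpm
        DataFrame indexed by gene ID with one column per replicate.  All
        values must be finite and non-negative (units: TPM).
    gene_types
        Optional gene ID -> biotype label map (``"protein_coding"``,
        ``"lincRNA"``, ...).  Every key must be a gene of the dataset.
    """

    dataset_id: str
    species: str
    tpm: pd.DataFrame
    gene_types: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.tpm.shape[1] < 1:
            raise ValidationError(
                f"dataset {self.dataset_id!r}: at least one replicate required"
            )
        dup = self.tpm.index[self.tpm.index.duplicated()]
        if len(dup):
            raise ValidationError(
                f"dataset {self.dataset_id!r}: duplicate gene ID {dup[0]!r}"
            )
        values = self.tpm.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError(
                f"dataset {self.dataset_id!r}: non-numeric TPM values"
            )
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"dataset {self.dataset_id!r}: non-finite TPM at gene "
                f"{self.tpm.index[r]!r}, replicate {self.tpm.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"dataset {self.dataset_id!r}: negative TPM at gene "
                f"{self.tpm.index[r]!r}, replicate {self.tpm.columns[c]!r}"
            )
        if self.gene_types is not None:
            unknown = set(self.gene_types) - set(self.tpm.index)
            if unknown:
                raise ValidationError(
                    f"dataset {self.dataset_id!r}: gene_types keys not in the "
                    f"dataset, e.g. {sorted(unknown)[0]!r}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def replicates(self) -> list[str]:
        return list(self.tpm.columns)

    @property
    def n_genes(self) -> int:
        return self.tpm.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.tpm.shape[1]

    def mean_tpm(self) -> pd.Series:
        """Arithmetic mean TPM per gene across replicates."""
        return self.tpm.mean(axis=1)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): set name -> (description, members)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_desc, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _desc, members in self.sets.values():
            out |= members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class ReferenceGeneList:
    """A named list of unique gene IDs (e.g. oocyte-specific genes)."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"reference list {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"reference list {self.name!r} has duplicates")

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)


def _strip_version(gene_id: str) -> str:
    base, dot, tail = gene_id.rpartition(".")
    if dot and tail.isdigit():
        return base
    return gene_id


def read_expression_matrix(
    path,
    dataset_id: str,
    species: str,
    gene_types: dict[str, str] | None = None,
    strip_id_version: bool = False,
) -> ExpressionDataset:
    """Read a TSV TPM matrix (header ``gene_id<TAB>rep1<TAB>rep2...``).

    Raises :class:`ParseError` on a malformed header and
    :class:`ValidationError` on non-numeric/negative values (naming the
    offending row and column) or duplicated gene IDs.
    """
    try:
        raw = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas failure messages vary
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if raw.shape[1] < 2:
        raise ParseError(
            f"{path}: expected a gene-ID column plus >=1 replicate column"
        )
    gene_col = raw.columns[0]
    genes = raw[gene_col].astype(str)
    if strip_id_version:
        genes = genes.map(_strip_version)
    dup = genes[genes.duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate gene ID {dup.iloc[0]!r}")
    body = raw.drop(columns=[gene_col])
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: non-numeric TPM value {body.iloc[r, c]!r} at gene "
            f"{genes.iloc[r]!r}, replicate {body.columns[c]!r}"
        )
    numeric.index = pd.Index(genes, name="gene_id")
    if gene_types is not None and strip_id_version:
        gene_types = {_strip_version(k): v for k, v in gene_types.items()}
    return ExpressionDataset(
        dataset_id=dataset_id, species=species, tpm=numeric, gene_types=gene_types
    )


def write_expression_matrix(ds: ExpressionDataset, path) -> None:
    """Write a dataset back to the TSV dialect ``read_expression_matrix`` reads."""
    out = ds.tpm.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            members = frozenset(f for f in fields[2:] if f)
            if name in sets:
                raise ValidationError(f"{path}: duplicate set name {name!r}")
            if not members:
                raise ParseError(f"{path}: line {lineno}: set {name!r} has no members")
            sets[name] = (desc, members)
    return GeneSetCollection(sets=sets)


def read_gene_list(path, name: str | None = None) -> ReferenceGeneList:
    """Read a one-gene-per-line list; blank lines and ``#`` comments ignored.

    Duplicate entries are collapsed (first occurrence wins), mirroring how
    published lists are reduced to unique gene IDs before use.
    """
    genes: list[str] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            if token not in seen:
                seen.add(token)
                genes.append(token)
    return ReferenceGeneList(name=name or str(path), genes=tuple(genes))


# ---------------------------------------------------------------------------
# Quantile-map export
# ---------------------------------------------------------------------------

_EXTRA_LABELS = ("unexpressed_partner", "no_ortholog")


def _axis_labels(n_quantiles: int) -> list[str]:
    return [f"q{i}" for i in range(1, n_quantiles + 1)] + list(_EXTRA_LABELS)


def write_quantile_map(qm, prefix, row_ds: ExpressionDataset | None = None,
                       col_ds: ExpressionDataset | None = None) -> None:
    """Write a quantile mapping as a TSV pair.

    ``<prefix>.counts.tsv``
        (n+2) x (n+2) integer count matrix; empty cells are written as ``0``.
    ``<prefix>.members.tsv``
        Long-format per-entry table: row label, column label, row gene, column
        gene, and (when the datasets are supplied) the per-replicate TPMs of
        both genes.  Skipped when the mapping carries no member lists.
    """
    labels = _axis_labels(qm.n_quantiles)
    counts = pd.DataFrame(qm.counts, index=labels, columns=labels, dtype=int)
    counts.index.name = f"{qm.row_dataset}\\{qm.col_dataset}"
    counts.to_csv(f"{prefix}.counts.tsv", sep="\t", lineterminator="\n")

    if qm.members is None:
        return
    rows: list[dict] = []
    for (r, c) in sorted(qm.members):
        for gene_row, gene_col in sorted(
            qm.members[(r, c)], key=lambda p: (p[0] or "", p[1] or "")
        ):
            rec = {
                "row": labels[r - 1],
                "col": labels[c - 1],
                "gene_row": gene_row or "",
                "gene_col": gene_col or "",
            }
            if row_ds is not None and gene_row in row_ds.tpm.index:
                for rep in row_ds.replicates:
                    rec[f"{qm.row_dataset}:{rep}"] = row_ds.tpm.at[gene_row, rep]
            if col_ds is not None and gene_col in col_ds.tpm.index:
                for rep in col_ds.replicates:
                    rec[f"{qm.col_dataset}:{rep}"] = col_ds.tpm.at[gene_col, rep]
            rows.append(rec)
    long = pd.DataFrame(rows)
    long.to_csv(f"{prefix}.members.tsv", sep="\t", index=False, lineterminator="\n")


def read_quantile_map_counts(path) -> pd.DataFrame:
    """Re-read a ``.counts.tsv`` written by :func:`write_quantile_map`."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if not np.issubdtype(counts.to_numpy().dtype, np.integer):
        raise ValidationError(f"{path}: count matrix must be integer-valued")
    if (counts.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative counts")
    return counts
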