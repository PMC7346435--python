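"""Many-to-many cross-species orthology with binary confidence.

The relation is consumed from a BioMart-style TSV export, never fetched live.
Each pair carries a binary confidence flag (1 = high, 0 = low); the relation
may be many-to-many in both directions and high-confidence filtering keeps
that structure (no collapsing to one-to-one).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import pandas as pd

from .errors import ValidationError

__all__ = [
    "OrthologyMap",
    "read_orthology",
    "filter_high_confidence",
    "orthologs_of",
]


@dataclass(frozen=True)
class OrthologyMap:
    """Deduplicated set of (gene_a, gene_b, confidence) pairs."""

    species_a: str
    species_b: str
    pairs: tuple[tuple[str, str, int], ...]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], int] = {}
        for ga, gb, conf in self.pairs:
            if conf not in (0, 1):
                raise ValidationError(
                    f"orthology pair ({ga!r}, {gb!r}): confidence {conf!r} not in {{0, 1}}"
                )
            prev = seen.get((ga, gb))
            if prev is not None and prev != conf:
                raise ValidationError(
                    f"orthology pair ({ga!r}, {gb!r}) listed with conflicting confidence"
                )
            seen[(ga, gb)] = conf
        deduped = tuple(sorted((a, b, c) for (a, b), c in seen.items()))
        object.__setattr__(self, "pairs", deduped)

    @cached_property
    def a_to_b(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for ga, gb, _ in self.pairs:
            out.setdefault(ga, set()).add(gb)
        return {k: frozenset(v) for k, v in out.items()}

    @cached_property
    def b_to_a(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for ga, gb, _ in self.pairs:
            out.setdefault(gb, set()).add(ga)
        return {k: frozenset(v) for k, v in out.items()}

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @cached_property
    def genes_a(self) -> frozenset[str]:
        return frozenset(ga for ga, _, _ in self.pairs)

    @cached_property
    def genes_b(self) -> frozenset[str]:
        return frozenset(gb for _, gb, _ in self.pairs)

    @property
    def n_high_confidence(self) -> int:
        return sum(1 for _, _, c in self.pairs if c == 1)

    def counts(self) -> dict[str, int]:
        """Headline counts: pairs, distinct genes per side, high-confidence pairs."""
        return {
            "n_pairs": self.n_pairs,
            "n_genes_a": len(self.genes_a),
            "n_genes_b": len(self.genes_b),
            "n_high_confidence": self.n_high_confidence,
        }


def read_orthology(
    path,
    species_a: str = "A",
    species_b: str = "B",
    confidence_col: str = "confidence",
) -> OrthologyMap:
    """Read an orthology TSV: ``gene_a<TAB>gene_b<TAB>confidence`` with header.

    The first two columns are the species-A and species-B gene IDs; the
    confidence column is located by name (falling back to the third column).
    Exact duplicate pairs are collapsed; confidence outside {0, 1} raises.
    """
    table = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if table.shape[1] < 3:
        raise ValidationError(
            f"{path}: expected >=3 columns (gene_a, gene_b, confidence)"
        )
    conf_col = confidence_col if confidence_col in table.columns else table.columns[2]
    pairs = []
    for ga, gb, conf in zip(
        table.iloc[:, 0], table.iloc[:, 1], table[conf_col]
    ):
        try:
            conf_int = int(conf)
        except ValueError as exc:
            raise ValidationError(
                f"{path}: confidence {conf!r} for pair ({ga!r}, {gb!r}) is not an integer"
            ) from exc
        pairs.append((str(ga), str(gb), conf_int))
    return OrthologyMap(species_a=species_a, species_b=species_b, pairs=tuple(pairs))


def filter_high_confidence(om: OrthologyMap) -> OrthologyMap:
    """Keep confidence-1 pairs only; many-to-many structure is preserved."""
    return OrthologyMap(
        species_a=om.species_a,
        species_b=om.species_b,
        pairs=tuple(p for p in om.pairs if p[2] == 1),
    )


def orthologs_of(om: OrthologyMap, gene: str, direction: str = "a_to_b") -> frozenset[str]:
    """Orthologs of ``gene`` in the given direction (``"a_to_b"`` or ``"b_to_a"``).

    Unknown genes yield the empty set: the expression matrices and the
    orthology table come from different universes, so absence is not an error.
    """
    if direction == "a_to_b":
        return om.a_to_b.get(gene, frozenset())
    if direction == "b_to_a":
        return om.b_to_a.get(gene, frozenset())
    raise ValidationError(f"direction must be 'a_to_b' or 'b_to_a', got {direction!r}")


def write_orthology(om: OrthologyMap, path) -> None:
    """Write the map in the TSV dialect :func:`read_orthology` reads."""
    frame = pd.DataFrame(om.pairs, columns=["gene_a", "gene_b", "confidence"])
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
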