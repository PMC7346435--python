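"""Gene-set over-representation with Fisher's exact test and the EASE score.

The EASE score is the conservative variant of the one-sided Fisher test used
by the DAVID annotation tool: the hit count is reduced by one before the
hypergeometric tail is evaluated, so single-gene categories can never be
significant and small categories are down-weighted.  Bonferroni correction
over the tested sets is reported as a separate column; the default
significance criterion is the raw EASE score at 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

from .errors import ValidationError
from .io import GeneSetCollection

__all__ = [
    "EnrichmentResult",
    "fisher_overrep",
    "ease_score",
    "enrich",
]


def _check_margins(hits: int, list_size: int, set_size: int, universe_size: int) -> None:
    if min(hits, list_size, set_size, universe_size) < 0:
        raise ValidationError("all margins must be non-negative")
    if universe_size == 0:
        raise ValidationError("empty universe")
    if hits > list_size or hits > set_size:
        raise ValidationError(
            f"hits={hits} exceeds list_size={list_size} or set_size={set_size}"
        )
    if list_size > universe_size or set_size > universe_size:
        raise ValidationError("list/set size exceeds the universe")
    if list_size + set_size - hits > universe_size:
        raise ValidationError("margins are inconsistent with the universe size")


def fisher_overrep(hits: int, list_size: int, set_size: int, universe_size: int) -> float:
    """One-sided over-representation p-value ``P(X >= hits)``.

    X is hypergeometric: the overlap of a ``list_size`` draw with a
    ``set_size`` category inside a ``universe_size`` universe.
    """
    _check_margins(hits, list_size, set_size, universe_size)
    return float(hypergeom.sf(hits - 1, universe_size, set_size, list_size))


def ease_score(hits: int, list_size: int, set_size: int, universe_size: int) -> float:
    """Fisher over-representation p with one hit removed (``max(hits-1, 0)``).

    Always >= the plain Fisher p; equals 1 whenever ``hits <= 1``.
    """
    _check_margins(hits, list_size, set_size, universe_size)
    return float(hypergeom.sf(max(hits - 1, 0) - 1, universe_size, set_size, list_size))


@dataclass
class EnrichmentResult:
    """Over-representation scores for one gene set."""

    set_name: str
    hits: int
    list_size: int
    set_size: int
    universe_size: int
    fisher_p: float
    ease_score: float
    bonferroni_ease: float
    significant: bool


def enrich(
    gene_list,
    collection: GeneSetCollection,
    universe=None,
    threshold: float = 0.05,
    use_bonferroni: bool = False,
) -> list[EnrichmentResult]:
    """Score every gene set with at least one hit against ``gene_list``.

    The universe defaults to all genes appearing in the collection plus the
    analyzed list.  Sets are restricted to the universe before counting.
    Bonferroni multiplies the EASE score by the number of sets with >= 1 hit;
    the significance flag applies ``threshold`` to the raw EASE score by
    default (set ``use_bonferroni=True`` to test the corrected one).
    Results are sorted by EASE score, ties broken by set name.
    """
    gene_list = frozenset(gene_list)
    if universe is None:
        universe = collection.all_genes() | gene_list
    universe = frozenset(universe)
    if not universe:
        raise ValidationError("empty universe")
    if not gene_list <= universe:
        missing = sorted(gene_list - universe)[0]
        raise ValidationError(f"list gene {missing!r} not in the universe")

    scored: list[EnrichmentResult] = []
    for name in collection.names:
        members = collection.members(name) & universe
        hits = len(gene_list & members)
        if hits == 0:
            continue
        fisher = fisher_overrep(hits, len(gene_list), len(members), len(universe))
        ease = ease_score(hits, len(gene_list), len(members), len(universe))
        scored.append(
            EnrichmentResult(
                set_name=name,
                hits=hits,
                list_size=len(gene_list),
                set_size=len(members),
                universe_size=len(universe),
                fisher_p=fisher,
                ease_score=ease,
                bonferroni_ease=ease,  # corrected below once m is known
                significant=False,
            )
        )
    m = len(scored)
    for res in scored:
        res.bonferroni_ease = min(1.0, res.ease_score * m)
        criterion = res.bonferroni_ease if use_bonferroni else res.ease_score
        res.significant = criterion <= threshold
    scored.sort(key=lambda r: (r.ease_score, r.set_name))
    return scored
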