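"""Synthetic paired-species expression studies with known ground truth.

The generator emulates the statistical shape of a three-dataset oocyte
comparison: two datasets from one species and one from another, three
replicates each, heavy-tailed TPM distributions with large zero and sub-1-TPM
fractions, and a many-to-many orthology relation with binary confidence.

Model
-----
Every gene receives a latent standard-normal expression score.  Orthologous
pairs are coupled through a Gaussian copula with correlation
``concordance_rho`` (boosted by ``concordance_bias_top`` when the driving
gene sits in the top expression stratum); datasets of the same species share
their species latent with pairwise correlation ``dataset_rho``.  Per dataset
the latent score is scaled to log2 expression by a spread calibrated
numerically (bisection on the realized draws) so that, after each replicate
is renormalised to one million TPM, the fraction of non-zero genes below
1 TPM matches the configured ``sub1_fraction``.  Structural zeros take the configured ``zero_fraction`` of
genes, preferentially the lowest-latent ones.  Replicate noise is
multiplicative log-normal with coefficient of variation ``replicate_cv``.

An optional planted set of very highly expressed genes (latent shifted by
``planted_effect_sd`` standard deviations) provides a known answer key for
the highly-expressed caller and the concordance pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .calls import fraction_below, make_call_set, zero_fraction
from .errors import ValidationError
from .io import ExpressionDataset
from .orthology import OrthologyMap
from .quantile_map import assign_quantiles, build_quantile_mapping, region_enrichment

__all__ = [
    "DatasetSpec",
    "SimulationConfig",
    "SimulatedStudy",
    "SimulationTruth",
    "RecoveryReport",
    "simulate",
    "recover_parameters",
]

TPM_TOTAL = 1_000_000.0


@dataclass(frozen=True)
class DatasetSpec:
    """Marginal shape of one simulated dataset."""

    dataset_id: str
    species: str
    zero_fraction: float
    sub1_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_fraction < 1.0:
            raise ValidationError(f"{self.dataset_id}: zero_fraction out of [0, 1)")
        if not self.zero_fraction <= self.sub1_fraction < 1.0:
            raise ValidationError(
                f"{self.dataset_id}: need zero_fraction <= sub1_fraction < 1"
            )


def _default_datasets() -> tuple[DatasetSpec, ...]:
    # Three-dataset design: zero-TPM fractions 75/65/45 % and sub-1-TPM
    # fractions 87/80/61 % for the two human sets and the zebrafish set.
    return (
        DatasetSpec("H1", "human", 0.75, 0.87),
        DatasetSpec("H2", "human", 0.65, 0.80),
        DatasetSpec("ZF", "zebrafish", 0.45, 0.61),
    )


def _default_biotypes() -> dict[str, float]:
    return {
        "protein_coding": 0.55,
        "lincRNA": 0.15,
        "pseudogene": 0.20,
        "Mt_rRNA": 0.02,
        "other": 0.08,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults describe the emulated study."""

    seed: int = 0
    n_genes_a: int = 24_000
    n_genes_b: int = 26_000
    species_a: str = "human"
    species_b: str = "zebrafish"
    n_replicates: int = 3
    datasets: tuple[DatasetSpec, ...] = field(default_factory=_default_datasets)
    orthology_fraction: float = 0.60       # of species-A protein-coding genes
    high_conf_fraction: float = 0.53       # of ortholog pairs (9809 / 18388)
    many_to_many_rate: float = 0.32        # extra edges per primary pair
    concordance_rho: float = 0.7
    concordance_bias_top: float = 0.2
    top_stratum_quantile: float = 0.8
    dataset_rho: float = 0.9               # same-species dataset coupling
    replicate_cv: float = 0.3
    zero_jitter: float = 0.5
    planted_high_fraction: float = 0.0     # of the largest expressed set
    planted_effect_sd: float = 4.0
    biotype_mix: dict[str, float] = field(default_factory=_default_biotypes)

    def __post_init__(self) -> None:
        for name in ("orthology_fraction", "high_conf_fraction",
                     "concordance_rho", "dataset_rho", "top_stratum_quantile"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} out of [0, 1]")
        if self.many_to_many_rate < 0 or self.concordance_bias_top < 0:
            raise ValidationError("rates must be non-negative")
        if self.replicate_cv < 0:
            raise ValidationError("replicate_cv must be non-negative")
        if not 0.0 <= self.planted_high_fraction < 1.0:
            raise ValidationError("planted_high_fraction out of [0, 1)")
        if self.n_replicates < 1:
            raise ValidationError("need >=1 replicate")
        species = {d.species for d in self.datasets}
        if not species <= {self.species_a, self.species_b}:
            raise ValidationError("dataset species must be species_a or species_b")
        ids = [d.dataset_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate dataset_id in config")
        total = sum(self.biotype_mix.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValidationError("biotype_mix must sum to 1")

    def n_genes(self, species: str) -> int:
        return self.n_genes_a if species == self.species_a else self.n_genes_b

    def expected_expressed(self, spec: DatasetSpec) -> float:
        g_nz = round(self.n_genes(spec.species) * (1 - spec.zero_fraction))
        p1 = _sub1_given_nonzero(spec)
        return g_nz * (1 - p1)


def _sub1_given_nonzero(spec: DatasetSpec) -> float:
    return (spec.sub1_fraction - spec.zero_fraction) / (1 - spec.zero_fraction)


def _calibrate_sdlog2(z_nonzero: np.ndarray, p1: float) -> float:
    """Spread (log2 units) making the realized sub-1-TPM fraction equal p1.

    After scaling the latent scores z by sigma and renormalising to one
    million TPM, a gene falls below 1 TPM iff ``sigma * z < log2(S / 1e6)``
    with ``S`` the realized total.  The spread is found by bisection on
    ``g(sigma) = sigma * q_p1(z) - log2(S(sigma) / 1e6)`` where ``q_p1`` is
    the empirical p1-quantile of the drawn scores, so the calibration is
    exact for the noiseless matrix regardless of how heavy the tail is.
    """
    if not 0.0 < p1 < 1.0:
        raise ValidationError(
            f"infeasible zero/sub-1 fractions: P(TPM<1 | TPM>0)={p1} must be in (0,1)"
        )
    if len(z_nonzero) >= TPM_TOTAL:
        raise ValidationError("more non-zero genes than total TPM units")
    z_star = float(np.quantile(z_nonzero, p1))

    def g(sigma: float) -> float:
        log_s = _log2_sum_exp2(sigma * z_nonzero)
        return sigma * z_star - (log_s - math.log2(TPM_TOTAL))

    lo, hi = 1e-6, 64.0
    if g(lo) <= 0 or g(hi) >= 0:
        raise ValidationError("infeasible fraction combination (no spread solves it)")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _log2_sum_exp2(y: np.ndarray) -> float:
    """log2 of sum of 2**y, overflow-safe."""
    m = float(y.max())
    return m + math.log2(np.exp2(y - m).sum())


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside the generated matrices."""

    latent: dict[str, pd.Series]                  # dataset -> z-scores
    planted_highly_expressed: dict[str, frozenset[str]]
    planted_concordant: frozenset[str]            # species-A gene IDs
    sdlog2: dict[str, float]


@dataclass
class SimulatedStudy:
    """Datasets, orthology and truth for one simulated study."""

    datasets: list[ExpressionDataset]
    orthology: OrthologyMap
    truth: SimulationTruth
    config: SimulationConfig

    def dataset(self, dataset_id: str) -> ExpressionDataset:
        for ds in self.datasets:
            if ds.dataset_id == dataset_id:
                return ds
        raise KeyError(dataset_id)


def simulate(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate one study; identical config and seed give identical output."""
    rng = np.random.default_rng(cfg.seed)

    genes_a = [f"GA{i:06d}" for i in range(1, cfg.n_genes_a + 1)]
    genes_b = [f"GB{i:06d}" for i in range(1, cfg.n_genes_b + 1)]
    biotypes = sorted(cfg.biotype_mix)
    probs = np.array([cfg.biotype_mix[b] for b in biotypes])
    probs = probs / probs.sum()
    type_a = rng.choice(biotypes, size=cfg.n_genes_a, p=probs)
    type_b = rng.choice(biotypes, size=cfg.n_genes_b, p=probs)

    # ---- orthology ------------------------------------------------------
    pc_a = np.flatnonzero(type_a == "protein_coding")
    pc_b = np.flatnonzero(type_b == "protein_coding")
    n_orth = int(round(cfg.orthology_fraction * len(pc_a)))
    if n_orth > len(pc_b):
        raise ValidationError("not enough species-B protein-coding genes for orthology")
    chosen_a = rng.choice(pc_a, size=n_orth, replace=False)
    chosen_b = rng.choice(pc_b, size=n_orth, replace=False)
    pair_a = [int(a) for a in chosen_a]
    pair_b = [int(b) for b in chosen_b]
    pair_set = set(zip(pair_a, pair_b))
    parent_of_b: dict[int, int] = {b: a for a, b in zip(pair_a, pair_b)}
    # many-to-many: extra edges from a primary A gene to either a fresh,
    # so-far-unpaired B gene (widening the B side) or an already paired one.
    unused_b = [int(b) for b in pc_b if b not in parent_of_b]
    rng.shuffle(unused_b)
    extra_mask = rng.random(n_orth) < cfg.many_to_many_rate
    for i in np.flatnonzero(extra_mask):
        a = int(chosen_a[i])
        if unused_b and rng.random() < 0.7:
            b = unused_b.pop()
            parent_of_b[b] = a
        else:
            b = int(chosen_b[rng.integers(n_orth)])
        if (a, b) in pair_set:
            continue
        pair_set.add((a, b))
        pair_a.append(a)
        pair_b.append(b)
    confidence = rng.binomial(1, cfg.high_conf_fraction, size=len(pair_a))

    # ---- latent scores --------------------------------------------------
    u = rng.standard_normal(cfg.n_genes_a)
    v = rng.standard_normal(cfg.n_genes_b)

    # planted species-A genes get their latent bump before the copula so
    # that orthologs inherit the high expression through the coupling
    planted_a_idx = np.empty(0, dtype=int)
    planted_b_idx = np.empty(0, dtype=int)
    if cfg.planted_high_fraction > 0:
        def n_planted(species: str) -> int:
            sizes = [cfg.expected_expressed(d) for d in cfg.datasets
                     if d.species == species]
            return int(round(cfg.planted_high_fraction * max(sizes))) if sizes else 0

        n_pa, n_pb = n_planted(cfg.species_a), n_planted(cfg.species_b)
        planted_a_idx = rng.choice(pc_a, size=min(n_pa, len(pc_a)), replace=False)
        u[planted_a_idx] = (
            cfg.planted_effect_sd + 0.15 * rng.standard_normal(len(planted_a_idx))
        )

    top_cut = norm.ppf(cfg.top_stratum_quantile)
    orth_b = np.fromiter(parent_of_b.keys(), dtype=int)
    parents = np.fromiter(parent_of_b.values(), dtype=int)
    rho = np.full(len(orth_b), cfg.concordance_rho)
    rho[u[parents] > top_cut] = np.minimum(
        1.0, cfg.concordance_rho + cfg.concordance_bias_top
    )
    v[orth_b] = rho * u[parents] + np.sqrt(1.0 - rho ** 2) * v[orth_b]

    if cfg.planted_high_fraction > 0:
        planted_a_set = set(int(i) for i in planted_a_idx)
        # every orthology partner of a planted gene is planted too, so the
        # copula cannot push non-truth genes to planted-level expression
        partners = sorted(
            {b for a, b in zip(pair_a, pair_b) if a in planted_a_set}
        )
        fill_pool = np.asarray(
            [b for b in pc_b if b not in set(partners)], dtype=int
        )
        n_fill = max(0, n_pb - len(partners))
        fill = rng.choice(fill_pool, size=min(n_fill, len(fill_pool)), replace=False)
        planted_b_idx = np.concatenate([np.asarray(partners, dtype=int), fill])
        v[planted_b_idx] = (
            cfg.planted_effect_sd + 0.15 * rng.standard_normal(len(planted_b_idx))
        )

    planted_a_set = set(int(i) for i in planted_a_idx)
    planted_b_set = set(int(i) for i in planted_b_idx)
    planted_concordant = frozenset(
        genes_a[a] for a, b, c in zip(pair_a, pair_b, confidence)
        if c == 1 and a in planted_a_set and b in planted_b_set
    )

    # ---- per-dataset matrices ------------------------------------------
    datasets: list[ExpressionDataset] = []
    latent: dict[str, pd.Series] = {}
    planted_high: dict[str, frozenset[str]] = {}
    sdlogs: dict[str, float] = {}
    s_rep = math.sqrt(math.log1p(cfg.replicate_cv ** 2))
    for spec in cfg.datasets:
        is_a = spec.species == cfg.species_a
        base = u if is_a else v
        names = genes_a if is_a else genes_b
        types = type_a if is_a else type_b
        g = len(base)
        rd = cfg.dataset_rho
        z = math.sqrt(rd) * base + math.sqrt(1.0 - rd) * rng.standard_normal(g)
        # planted genes sit at the configured effect size in every dataset;
        # without this the dataset-level noise would dilute the planted shift
        planted_idx = planted_a_idx if is_a else planted_b_idx
        if len(planted_idx):
            z[planted_idx] = (
                cfg.planted_effect_sd + 0.15 * rng.standard_normal(len(planted_idx))
            )
        n_zero = int(round(spec.zero_fraction * g))
        zero_idx = np.argsort(z + cfg.zero_jitter * rng.standard_normal(g),
                              kind="stable")[:n_zero]
        nonzero = np.ones(g, dtype=bool)
        nonzero[zero_idx] = False
        sigma = _calibrate_sdlog2(z[nonzero], _sub1_given_nonzero(spec))
        sdlogs[spec.dataset_id] = sigma
        w = np.exp2(np.clip(sigma * z, None, 1000.0))
        w[zero_idx] = 0.0
        cols = {}
        for r in range(cfg.n_replicates):
            if s_rep > 0:
                noise = np.exp(rng.normal(-0.5 * s_rep ** 2, s_rep, size=g))
                col = w * noise
            else:
                col = w.copy()
            total = col.sum()
            if total <= 0:
                raise ValidationError(f"{spec.dataset_id}: all-zero replicate")
            cols[f"{spec.dataset_id.lower()}{chr(ord('a') + r)}"] = TPM_TOTAL * col / total
        tpm = pd.DataFrame(cols, index=pd.Index(names, name="gene_id"))
        datasets.append(
            ExpressionDataset(
                dataset_id=spec.dataset_id,
                species=spec.species,
                tpm=tpm,
                gene_types=dict(zip(names, types)),
            )
        )
        latent[spec.dataset_id] = pd.Series(z, index=names)
        idx = planted_a_idx if is_a else planted_b_idx
        planted_high[spec.dataset_id] = frozenset(names[int(i)] for i in idx)

    orthology = OrthologyMap(
        species_a=cfg.species_a,
        species_b=cfg.species_b,
        pairs=tuple(
            (genes_a[a], genes_b[b], int(c))
            for a, b, c in zip(pair_a, pair_b, confidence)
        ),
    )
    truth = SimulationTruth(
        latent=latent,
        planted_highly_expressed=planted_high,
        planted_concordant=planted_concordant,
        sdlog2=sdlogs,
    )
    return SimulatedStudy(datasets=datasets, orthology=orthology,
                          truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Planted-vs-detected and configured-vs-observed summaries."""

    dataset_stats: pd.DataFrame
    cross_maps: dict[tuple[str, str], dict[str, float]]


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def recover_parameters(
    study: SimulatedStudy,
    tpm_threshold: float = 1.0,
    z_threshold: float = 1.5,
    n_quantiles: int = 10,
    k: int = 3,
) -> RecoveryReport:
    """Re-run the calling and mapping stages and compare against the truth.

    Reports, per dataset, the observed zero and sub-1-TPM fractions, the
    expressed count, and (when genes were planted) the Jaccard overlap of the
    planted and detected highly-expressed sets; and per cross-species dataset
    pair the (1,1)-cell and top ``k x k`` odds ratios with one-sided p-values.
    """
    cfg = study.config
    rows = []
    call_sets = {}
    for ds, spec in zip(study.datasets, cfg.datasets):
        cs = make_call_set(ds, tpm_threshold=tpm_threshold, z_threshold=z_threshold)
        call_sets[ds.dataset_id] = cs
        planted = study.truth.planted_highly_expressed[ds.dataset_id]
        rows.append({
            "dataset_id": ds.dataset_id,
            "zero_fraction_observed": float(zero_fraction(ds).mean()),
            "zero_fraction_config": spec.zero_fraction,
            "sub1_fraction_observed": float(fraction_below(ds, 1.0).mean()),
            "sub1_fraction_config": spec.sub1_fraction,
            "n_expressed": len(cs.expressed),
            "n_highly_expressed": len(cs.highly_expressed),
            "planted_jaccard": (
                _jaccard(planted, cs.highly_expressed) if planted else float("nan")
            ),
        })
    stats = pd.DataFrame(rows).set_index("dataset_id")

    cross: dict[tuple[str, str], dict[str, float]] = {}
    a_sets = [d for d in cfg.datasets if d.species == cfg.species_a]
    b_sets = [d for d in cfg.datasets if d.species == cfg.species_b]
    for da in a_sets:
        for db in b_sets:
            qa = assign_quantiles(call_sets[da.dataset_id], n_quantiles)
            qb = assign_quantiles(call_sets[db.dataset_id], n_quantiles)
            qm = build_quantile_mapping(qa, qb, om=study.orthology, row_side="a")
            top = region_enrichment(qm, [1], [1], alternative="greater")
            corner = region_enrichment(qm, range(1, k + 1), range(1, k + 1),
                                       alternative="greater")
            cross[(da.dataset_id, db.dataset_id)] = {
                "n_grid_pairs": qm.n_grid_pairs,
                "top_cell_observed": top.observed,
                "top_cell_expected": top.expected,
                "top_cell_odds_ratio": top.odds_ratio,
                "top_cell_p": top.p_value,
                "corner_observed": corner.observed,
                "corner_expected": corner.expected,
                "corner_odds_ratio": corner.odds_ratio,
                "corner_p": corner.p_value,
            }
    return RecoveryReport(dataset_stats=stats, cross_maps=cross)


def config_to_dict(cfg: SimulationConfig) -> dict:
    """Plain-dict form of a config (YAML/JSON friendly)."""
    out = asdict(cfg)
    out["datasets"] = [asdict(d) for d in cfg.datasets]
    return out


def config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data)
    if "datasets" in data:
        data["datasets"] = tuple(
            d if isinstance(d, DatasetSpec) else DatasetSpec(**d)
            for d in data["datasets"]
        )
    return SimulationConfig(**data)
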