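"""Sample-similarity statistics on a chosen gene set.

Workflow mirrored from the field's standard practice for cross-dataset
comparisons of a handful of samples:

1. row-normalize the genes x samples signal matrix (each gene to mean 0,
   SD 1 across samples);
2. UPGMA (average-linkage) clustering of samples with Pearson distance
   ``d(i, j) = 1 - r(i, j)``;
3. PCA of the samples with the percent variance per component;
4. ANOSIM and adonis (PERMANOVA) permutation tests of dataset labels on
   Euclidean distances over the retained PC scores (all PCs by default).

Both permutation tests switch automatically to exhaustive enumeration of the
distinct label assignments when there are at most ``EXHAUSTIVE_LIMIT`` of
them, which makes small designs (6 or 9 samples) exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.decomposition import PCA

from .errors import ValidationError

__all__ = [
    "PermutationTestResult",
    "UpgmaResult",
    "PcaResult",
    "row_normalize",
    "pearson_distances",
    "upgma_cluster",
    "pca_scores",
    "pc_distances",
    "anosim",
    "adonis",
]

EXHAUSTIVE_LIMIT = 10_000


def row_normalize(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Scale every row (gene) to mean 0 and SD 1 across samples."""
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=ddof)
    if (sd == 0).any() or not np.isfinite(sd).all():
        gene = matrix.index[int(np.argwhere((sd == 0) | ~np.isfinite(sd))[0][0])]
        raise ValidationError(f"zero-variance row for gene {gene!r}")
    out = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def pearson_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample-by-sample distance ``1 - Pearson r`` between matrix columns."""
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=0)
    if (sd == 0).any():
        col = matrix.columns[int(np.argwhere(sd == 0)[0][0])]
        raise ValidationError(f"constant sample column {col!r}: correlation undefined")
    corr = np.corrcoef(values, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=matrix.columns, columns=matrix.columns)


@dataclass
class UpgmaResult:
    """Average-linkage dendrogram over samples."""

    labels: tuple[str, ...]
    linkage: np.ndarray  # scipy linkage matrix
    distances: pd.DataFrame

    def cophenetic(self) -> pd.DataFrame:
        coph = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(coph, index=self.labels, columns=self.labels)

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = node.get_left(), node.get_right()
            parts = []
            for child in (left, right):
                length = node.dist - (0.0 if child.is_leaf() else child.dist)
                parts.append(f"{walk(child)}:{length:.6g}")
            return f"({parts[0]},{parts[1]})"

        return walk(tree) + ";"


def upgma_cluster(matrix: pd.DataFrame, normalize: bool = True) -> UpgmaResult:
    """UPGMA clustering of samples with 1 - Pearson distance.

    The matrix is row-normalized first (disable with ``normalize=False`` if it
    already is).  Merge heights are non-decreasing, a UPGMA guarantee.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("need >=2 samples to cluster")
    work = row_normalize(matrix) if normalize else matrix
    dist = pearson_distances(work)
    linkage = hierarchy.linkage(squareform(dist.to_numpy(), checks=False),
                                method="average")
    return UpgmaResult(labels=tuple(matrix.columns), linkage=linkage, distances=dist)


@dataclass
class PcaResult:
    """Sample coordinates on principal components plus variance fractions."""

    scores: pd.DataFrame  # samples x PCs
    explained_variance_ratio: np.ndarray


def pca_scores(matrix: pd.DataFrame, n_components: int = 2) -> PcaResult:
    """Centered PCA of the samples (columns) of a genes x samples matrix."""
    n_samples, n_features = matrix.shape[1], matrix.shape[0]
    if n_samples < 2:
        raise ValidationError("need >=2 samples for PCA")
    max_rank = min(n_samples, n_features)
    if n_components > max_rank:
        raise ValidationError(
            f"n_components={n_components} exceeds the rank bound {max_rank}"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(matrix.to_numpy(dtype=float).T)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=cols),
        explained_variance_ratio=model.explained_variance_ratio_,
    )


def pc_distances(matrix: pd.DataFrame, n_components: int | None = None) -> pd.DataFrame:
    """Euclidean sample distances on PC scores (all PCs by default).

    With all components retained this equals the Euclidean distance on the
    centered data, so it is the natural input for ANOSIM/adonis "applied to
    PCA results".
    """
    if n_components is None:
        n_components = min(matrix.shape[1] - 1, matrix.shape[0])
        n_components = max(n_components, 1)
    res = pca_scores(matrix, n_components=n_components)
    pts = res.scores.to_numpy()
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    return pd.DataFrame(dist, index=matrix.columns, columns=matrix.columns)


@dataclass
class PermutationTestResult:
    """Result of a label-permutation test on a distance matrix."""

    statistic_name: str
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None
    method: str  # "permutation" | "exhaustive"


def _check_groups(labels: np.ndarray) -> None:
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("need >=2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2][0]
        raise ValidationError(f"group {small!r} has fewer than 2 samples")


def _as_labels(dist: pd.DataFrame | np.ndarray, groups) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dist, pd.DataFrame):
        names = list(dist.columns)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        names = list(range(d.shape[0]))
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    if isinstance(groups, dict):
        try:
            labels = np.asarray([groups[s] for s in names], dtype=object)
        except KeyError as exc:
            raise ValidationError(f"no group label for sample {exc.args[0]!r}") from exc
    else:
        labels = np.asarray(list(groups), dtype=object)
        if len(labels) != d.shape[0]:
            raise ValidationError("groups length does not match the distance matrix")
    _check_groups(labels)
    return d, labels


def _n_distinct_assignments(labels: np.ndarray) -> int:
    _, counts = np.unique(labels, return_counts=True)
    total = math.factorial(len(labels))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def _multiset_permutations(items: list):
    """Yield all distinct permutations of a multiset, lexicographically."""
    pool = sorted(items)
    n = len(pool)
    out: list = []

    def rec(remaining: list):
        if len(out) == n:
            yield tuple(out)
            return
        prev = object()
        for i, x in enumerate(remaining):
            if x == prev:
                continue
            prev = x
            out.append(x)
            yield from rec(remaining[:i] + remaining[i + 1:])
            out.pop()

    yield from rec(pool)


def _permutation_test(
    d: np.ndarray,
    labels: np.ndarray,
    stat_fn,
    statistic_name: str,
    n_permutations: int,
    seed: int | None,
    exhaustive: bool | None,
) -> PermutationTestResult:
    observed = stat_fn(labels)
    if exhaustive is None:
        exhaustive = _n_distinct_assignments(labels) <= EXHAUSTIVE_LIMIT
    eps = 1e-12
    if exhaustive:
        total = 0
        ge = 0
        for perm in _multiset_permutations(list(labels)):
            total += 1
            if stat_fn(np.asarray(perm, dtype=object)) >= observed - eps:
                ge += 1
        return PermutationTestResult(
            statistic_name=statistic_name,
            statistic=float(observed),
            p_value=ge / total,
            n_permutations=total,
            seed=seed,
            method="exhaustive",
        )
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if stat_fn(perm) >= observed - eps:
            ge += 1
    return PermutationTestResult(
        statistic_name=statistic_name,
        statistic=float(observed),
        p_value=(1 + ge) / (n_permutations + 1),
        n_permutations=n_permutations,
        seed=seed,
        method="permutation",
    )


def anosim(
    dist,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> PermutationTestResult:
    """Analysis of similarity (Clarke's R) with a permutation p-value.

    ``R = (mean between-group rank - mean within-group rank) / (M / 2)`` with
    ``M = n(n-1)/2`` ranks over all sample pairs; R lies in [-1, 1] and the
    p-value is the fraction of label assignments with R at least as large.
    """
    d, labels = _as_labels(dist, groups)
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])
    denom = (n * (n - 1) / 2) / 2.0

    def stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    return _permutation_test(
        d, labels, stat, "ANOSIM R", n_permutations, seed, exhaustive
    )


def adonis(
    dist,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> PermutationTestResult:
    """One-way adonis / PERMANOVA R^2 with a permutation p-value.

    ``R^2 = SS_between / SS_total`` from the Gower-centered distance
    partition: ``SS_total = sum d_ij^2 / n`` over i<j and ``SS_within`` the
    analogous per-group sums.  R^2 is scale-invariant and lies in [0, 1];
    for fixed group sizes its permutation distribution orders identically to
    the pseudo-F statistic.
    """
    d, labels = _as_labels(dist, groups)
    n = d.shape[0]
    d2 = d ** 2
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    if ss_total == 0:
        raise ValidationError("all distances are zero; R^2 undefined")

    def stat(lab: np.ndarray) -> float:
        ss_within = 0.0
        for g in np.unique(lab):
            idx = np.flatnonzero(lab == g)
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
        return 1.0 - ss_within / ss_total

    return _permutation_test(
        d, labels, stat, "adonis R2", n_permutations, seed, exhaustive
    )
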