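"""Row normalization, UPGMA, PCA, ANOSIM and adonis, with brute oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from orthoquant.errors import ValidationError
from orthoquant.similarity import (
    adonis,
    anosim,
    pc_distances,
    pca_scores,
    pearson_distances,
    row_normalize,
    upgma_cluster,
)


def euclid(points, labels):
    d = squareform(pdist(np.asarray(points, dtype=float)))
    return pd.DataFrame(d, index=labels, columns=labels)


class TestRowNormalize:
    def test_simple_row(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        out = row_normalize(m)
        assert out.loc["g"].mean() == pytest.approx(0.0)
        assert out.loc["g"].std(ddof=1) == pytest.approx(1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(20, 6)))
        once = row_normalize(m)
        twice = row_normalize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_random_matrix_all_rows_standardized(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(50, 9)))
        out = row_normalize(m).to_numpy()
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_constant_row_named_in_error(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                         index=["flat", "ok"])
        with pytest.raises(ValidationError, match="flat"):
            row_normalize(m)


def naive_upgma(dist):
    """Text-book UPGMA agglomeration; returns merge list [(set, set, height)]."""
    clusters = {i: frozenset([i]) for i in range(dist.shape[0])}
    d = {(i, j): dist[i, j] for i in range(dist.shape[0])
         for j in range(i + 1, dist.shape[0])}
    merges = []
    next_id = dist.shape[0]
    while len(clusters) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        merged = clusters[i] | clusters[j]
        merges.append((clusters[i], clusters[j], h))
        del clusters[i], clusters[j]
        new_d = {}
        for (a, b), val in d.items():
            if i in (a, b) or j in (a, b):
                continue
            new_d[(a, b)] = val
        for k, members in clusters.items():
            num = 0.0
            for m in members:
                for x in merged:
                    num += dist[m, x]
            new_d[tuple(sorted((k, next_id)))] = num / (len(members) * len(merged))
        clusters[next_id] = merged
        d = new_d
        next_id += 1
    return merges


class TestUpgma:
    def test_identical_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=12)
        m = pd.DataFrame({"s1": base, "s2": base, "s3": rng.normal(size=12)})
        res = upgma_cluster(m)
        first = res.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_merge_order_and_heights_match_naive_agglomeration(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("wxyz"))
        res = upgma_cluster(m)
        dist = res.distances.to_numpy()
        merges = naive_upgma(dist)
        # same merge heights in the same order
        assert np.allclose(res.linkage[:, 2], [h for _, _, h in merges])
        # same final topology: compare the first merged pair
        first = {int(res.linkage[0][0]), int(res.linkage[0][1])}
        assert first == set(merges[0][0] | merges[0][1])

    def test_cophenetic_distances_are_ultrametric(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(size=(25, 6)))
        coph = upgma_cluster(m).cophenetic().to_numpy()
        n = coph.shape[0]
        for i, j, k in itertools.combinations(range(n), 3):
            triple = sorted([coph[i, j], coph[i, k], coph[j, k]])
            assert triple[2] <= triple[1] + 1e-9   # two largest are equal

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(10)
        m = pd.DataFrame(rng.normal(size=(40, 8)))
        heights = upgma_cluster(m).linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_constant_column_rejected(self):
        m = pd.DataFrame({"s1": [1.0, 2.0, 4.0], "s2": [1.0, 1.0, 1.0]})
        with pytest.raises(ValidationError):
            pearson_distances(m)

    def test_newick_contains_all_labels(self):
        rng = np.random.default_rng(12)
        m = pd.DataFrame(rng.normal(size=(15, 5)),
                         columns=["h1a", "h1b", "h2a", "h2b", "zfa"])
        nwk = upgma_cluster(m).to_newick()
        for label in m.columns:
            assert label in nwk


class TestPca:
    def test_collinear_samples_put_all_variance_on_pc1(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        m = pd.DataFrame(np.outer(np.array([1.0, -2.0, 0.5]), t))
        res = pca_scores(m, n_components=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)
        assert res.explained_variance_ratio[1] == pytest.approx(0.0, abs=1e-12)

    def test_variance_fractions_match_covariance_eigenvalues(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(30, 7)))
        res = pca_scores(m, n_components=5)
        x = m.to_numpy().T
        xc = x - x.mean(axis=0)
        eig = np.linalg.eigvalsh(xc @ xc.T)[::-1]
        frac = eig / eig.sum()
        assert np.allclose(res.explained_variance_ratio, frac[:5], atol=1e-10)

    def test_fractions_non_increasing_and_bounded(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(size=(30, 6)))
        res = pca_scores(m, n_components=4)
        ratios = res.explained_variance_ratio
        assert np.all(np.diff(ratios) <= 1e-12)
        assert ratios.sum() <= 1.0 + 1e-12

    def test_excessive_components_rejected(self):
        m = pd.DataFrame(np.eye(4)[:, :3])
        with pytest.raises(ValidationError):
            pca_scores(m, n_components=5)


def anosim_oracle(dist, labels):
    """Clarke's R computed independently from the definition."""
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    iu = np.triu_indices(n, 1)
    ranks = rankdata(d[iu])
    lab = np.asarray(labels)
    within = lab[iu[0]] == lab[iu[1]]
    m = n * (n - 1) / 2
    return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)


def exhaustive_p(dist, labels, stat_fn):
    """p-value by full enumeration of distinct label orderings."""
    labels = list(labels)
    obs = stat_fn(dist, labels)
    perms = set(itertools.permutations(labels))
    ge = sum(1 for p in perms if stat_fn(dist, list(p)) >= obs - 1e-12)
    return ge / len(perms)


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        pts = [[0, 0], [0.1, 0], [0, 0.1], [10, 10], [10.1, 10], [10, 10.1]]
        dist = euclid(pts, list("abcdef"))
        res = anosim(dist, ["g1"] * 3 + ["g2"] * 3)
        assert res.statistic == pytest.approx(1.0)
        assert res.method == "exhaustive"
        assert res.p_value == pytest.approx(2 / 20)  # 2 of 20 orderings tie R=1

    def test_statistic_matches_independent_definition(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(8, 3))
        labels = ["a"] * 4 + ["b"] * 4
        dist = euclid(pts, range(8))
        res = anosim(dist, labels, exhaustive=False, n_permutations=49, seed=1)
        assert res.statistic == pytest.approx(anosim_oracle(dist, labels))

    def test_exhaustive_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(1.5, 1, (3, 2))])
        labels = ["a"] * 3 + ["b"] * 3
        dist = euclid(pts, range(6))
        res = anosim(dist, labels)  # 20 assignments -> exhaustive mode
        assert res.method == "exhaustive"
        assert res.p_value == pytest.approx(
            exhaustive_p(dist.to_numpy(), labels, anosim_oracle)
        )

    def test_permutation_p_close_to_exhaustive(self):
        rng = np.random.default_rng(17)
        pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(2, 1, (3, 2)),
                         rng.normal(4, 1, (3, 2))])
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        dist = euclid(pts, range(9))
        exact = anosim(dist, labels, exhaustive=True)
        mc = anosim(dist, labels, exhaustive=False, n_permutations=999, seed=5)
        assert exact.n_permutations == 1680
        assert abs(exact.p_value - mc.p_value) <= 2 / math.sqrt(999)

    def test_null_labels_give_small_r(self):
        rng = np.random.default_rng(23)
        pts = rng.normal(size=(12, 4))
        dist = euclid(pts, range(12))
        res = anosim(dist, ["a", "b", "c"] * 4, exhaustive=False,
                     n_permutations=199, seed=2)
        assert abs(res.statistic) < 0.5
        assert res.p_value > 0.01

    def test_invariance_to_sample_reordering(self):
        rng = np.random.default_rng(31)
        pts = rng.normal(size=(8, 3))
        labels = ["a"] * 4 + ["b"] * 4
        dist = euclid(pts, [f"s{i}" for i in range(8)])
        perm = rng.permutation(8)
        dist2 = dist.iloc[perm, perm]
        groups = {f"s{i}": labels[i] for i in range(8)}
        r1 = anosim(dist, groups, exhaustive=True)
        r2 = anosim(dist2, groups, exhaustive=True)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_rank_based_scale_invariance(self):
        rng = np.random.default_rng(37)
        pts = rng.normal(size=(8, 3))
        labels = ["a"] * 4 + ["b"] * 4
        dist = euclid(pts, range(8))
        r1 = anosim(dist, labels, exhaustive=True)
        r2 = anosim(dist * 7.5, labels, exhaustive=True)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_singleton_group_rejected(self):
        dist = euclid(np.eye(4), range(4))
        with pytest.raises(ValidationError):
            anosim(dist, ["a", "a", "a", "b"])


def adonis_r2_oracle(points, labels):
    """Classical one-way MANOVA trace ratio SSB/SST from coordinates."""
    x = np.asarray(points, dtype=float)
    lab = np.asarray(labels)
    grand = x.mean(axis=0)
    sst = ((x - grand) ** 2).sum()
    ssw = 0.0
    for g in np.unique(lab):
        sub = x[lab == g]
        ssw += ((sub - sub.mean(axis=0)) ** 2).sum()
    return (sst - ssw) / sst


class TestAdonis:
    def test_euclidean_r2_equals_manova_trace_ratio(self):
        rng = np.random.default_rng(41)
        pts = np.vstack([rng.normal(0, 1, (3, 4)), rng.normal(1, 1, (3, 4)),
                         rng.normal(2, 1, (3, 4))])
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        dist = euclid(pts, range(9))
        res = adonis(dist, labels, exhaustive=True)
        assert res.statistic == pytest.approx(adonis_r2_oracle(pts, labels))

    def test_tight_groups_drive_r2_to_one(self):
        pts = np.repeat(np.array([[0.0, 0], [5, 5], [9, 1]]), 3, axis=0)
        pts = pts + np.random.default_rng(2).normal(0, 1e-6, pts.shape)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = adonis(euclid(pts, range(9)), labels, exhaustive=True)
        assert res.statistic > 0.999

    def test_shuffled_labels_near_null(self):
        rng = np.random.default_rng(43)
        pts = rng.normal(size=(12, 5))
        labels = rng.permutation(["a", "b", "c"] * 4)
        res = adonis(euclid(pts, range(12)), list(labels), exhaustive=False,
                     n_permutations=199, seed=3)
        assert res.statistic < 0.5
        assert res.p_value > 0.01

    def test_scale_invariance_of_r2(self):
        rng = np.random.default_rng(47)
        pts = rng.normal(size=(8, 3))
        labels = ["a"] * 4 + ["b"] * 4
        r1 = adonis(euclid(pts, range(8)), labels, exhaustive=True)
        r2 = adonis(euclid(pts, range(8)) * 3.0, labels, exhaustive=True)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_p_value_bounded_below_by_design(self):
        rng = np.random.default_rng(53)
        pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(9, 1, (3, 2))])
        labels = ["a"] * 3 + ["b"] * 3
        res = adonis(euclid(pts, range(6)), labels)
        assert res.p_value >= 1 / (res.n_permutations + 1)


class TestAgainstScikitBio:
    def _fixture(self):
        rng = np.random.default_rng(61)
        pts = np.vstack([rng.normal(0, 1, (3, 3)), rng.normal(1.5, 1, (3, 3)),
                         rng.normal(3, 1, (3, 3))])
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        ids = [f"s{i}" for i in range(9)]
        return euclid(pts, ids), labels, ids

    def test_anosim_statistic_matches_skbio(self):
        pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.stats.distance import anosim as sk_anosim
        dist, labels, ids = self._fixture()
        ours = anosim(dist, labels, exhaustive=True)
        theirs = sk_anosim(DistanceMatrix(dist.to_numpy(), ids), labels,
                           permutations=99)
        assert ours.statistic == pytest.approx(theirs["test statistic"])

    def test_adonis_r2_consistent_with_skbio_pseudo_f(self):
        pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova
        dist, labels, ids = self._fixture()
        ours = adonis(dist, labels, exhaustive=True)
        theirs = permanova(DistanceMatrix(dist.to_numpy(), ids), labels,
                           permutations=99)
        f = theirs["test statistic"]
        n, k = 9, 3
        r2_from_f = (f * (k - 1)) / (f * (k - 1) + (n - k))
        assert ours.statistic == pytest.approx(r2_from_f)


class TestMonotoneShiftRecovery:
    def test_statistics_increase_with_group_separation(self):
        rng = np.random.default_rng(71)
        base = rng.normal(size=(9, 3))
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        r_vals, r2_vals = [], []
        for shift in (0.0, 1.0, 2.0, 4.0):
            pts = base + shift * np.repeat(np.eye(3), 3, axis=0)
            dist = euclid(pts, range(9))
            r_vals.append(anosim(dist, labels, exhaustive=True).statistic)
            r2_vals.append(adonis(dist, labels, exhaustive=True).statistic)
        assert all(b >= a - 1e-9 for a, b in zip(r_vals, r_vals[1:]))
        assert all(b >= a - 1e-9 for a, b in zip(r2_vals, r2_vals[1:]))


class TestPcDistances:
    def test_all_pcs_reproduce_centered_euclidean(self):
        rng = np.random.default_rng(81)
        m = pd.DataFrame(rng.normal(size=(20, 6)))
        d_pc = pc_distances(m).to_numpy()
        x = m.to_numpy().T
        d_raw = squareform(pdist(x - x.mean(axis=0)))
        assert np.allclose(d_pc, d_raw, atol=1e-8)
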