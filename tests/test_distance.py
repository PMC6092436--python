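"""Bray-Curtis, NMDS, ANOSIM and (partial) Mantel behaviour."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from abundrare import (
    DataError, DistanceMatrix, anosim, bray_curtis, mantel, nmds,
    partial_mantel,
)
from conftest import ra_from


def dm_from_points(pts, labels=None):
    d = squareform(pdist(pts))
    labels = labels or [f"s{i}" for i in range(len(pts))]
    return DistanceMatrix(labels, d)


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        ra = ra_from(np.array([[4, 4, 0], [1, 1, 0], [0, 0, 5]]))
        d = bray_curtis(ra, transform="none")
        assert d.values[0, 1] == pytest.approx(0.0)
        assert d.values[0, 2] == pytest.approx(1.0)

    def test_sqrt_transform_hand_value(self):
        # columns [4,1] vs [1,4]: sqrt -> [2,1] vs [1,2]; BC = 2/6
        ra = ra_from(np.array([[4, 1], [1, 4]]))
        d = bray_curtis(ra, transform="none")  # ra already normalised; use raw counts below
        from abundrare import RelAbundanceMatrix

        # build directly on unnormalised sqrt values via a 2-sample count matrix
        x = np.array([[4, 1], [1, 4]], dtype=float)
        bc = np.abs(np.sqrt(x[:, 0]) - np.sqrt(x[:, 1])).sum() / (np.sqrt(x[:, 0]) + np.sqrt(x[:, 1])).sum()
        assert bc == pytest.approx(1 / 3)
        ra2 = RelAbundanceMatrix(["a", "b"], ["s0", "s1"], x / x.sum(axis=0))
        d2 = bray_curtis(ra2, transform="sqrt")
        assert d2.values[0, 1] == pytest.approx(1 / 3)

    def test_matches_skbio(self):
        pytest.importorskip("skbio")
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, (20, 6))
        counts[0] += 1
        ra = ra_from(counts)
        mine = bray_curtis(ra, transform="none")
        ref = beta_diversity("braycurtis", ra.ra.T, ids=ra.sample_ids)
        assert np.allclose(mine.values, ref.data, atol=1e-12)


class TestNMDS:
    def test_perfect_embedding_low_stress(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 2))
        res = nmds(dm_from_points(pts), k=2, n_starts=8, seed=0)
        assert res.stress < 0.01

    def test_equidistant_simplex_cannot_embed(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(list("abcd"), d)
        stresses = [nmds(dm, k=2, n_starts=10, seed=s).stress for s in (0, 1)]
        assert all(s > 1e-4 for s in stresses)
        assert abs(stresses[0] - stresses[1]) < 1e-3

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        dm = dm_from_points(rng.normal(size=(8, 3)))
        a = nmds(dm, n_starts=1, seed=5)
        b = nmds(dm, n_starts=1, seed=5)
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_k_too_large(self):
        dm = dm_from_points(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(DataError):
            nmds(dm, k=4)


class TestANOSIM:
    def test_complete_separation_r_is_one(self):
        pts = np.vstack([np.zeros((3, 2)) + np.random.default_rng(0).normal(0, 0.01, (3, 2)),
                         np.full((3, 2), 10) + np.random.default_rng(1).normal(0, 0.01, (3, 2))])
        res = anosim(dm_from_points(pts), ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_null_r_centres_on_zero(self):
        rng = np.random.default_rng(3)
        rs = []
        for _ in range(50):
            dm = dm_from_points(rng.normal(size=(10, 3)))
            g = rng.permutation(["a"] * 5 + ["b"] * 5)
            rs.append(anosim(dm, g, n_perm=9, seed=int(rng.integers(2**31))).R)
        assert abs(np.mean(rs)) < 0.1

    def test_p_matches_full_enumeration(self):
        # n = 6, groups of 3: statistic is invariant under within-group swaps,
        # so enumerate all C(6,3)/1 distinct labelings for the exact null
        rng = np.random.default_rng(4)
        dm = dm_from_points(rng.normal(size=(6, 2)))
        groups = np.array(["a", "a", "a", "b", "b", "b"], dtype=object)
        from scipy.stats import rankdata

        ranks = rankdata(squareform(dm.values, checks=False))
        i, j = np.triu_indices(6, 1)

        def r_of(g):
            w = g[i] == g[j]
            return (ranks[~w].mean() - ranks[w].mean()) / (len(ranks) / 2)

        r_obs = r_of(groups)
        null = []
        for combo in itertools.combinations(range(6), 3):
            g = np.array(["b"] * 6, dtype=object)
            for c in combo:
                g[c] = "a"
            null.append(r_of(g))
        exact_p = (np.sum(np.array(null) >= r_obs - 1e-12)) / len(null)
        res = anosim(dm, groups, n_perm=4999, seed=0)
        assert res.p == pytest.approx(exact_p, abs=0.03)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        dm = dm_from_points(rng.normal(size=(8, 2)))
        g = ["a"] * 4 + ["b"] * 4
        r1 = anosim(dm, g, n_perm=9, seed=1).R
        dm2 = DistanceMatrix(dm.labels, dm.values**2)  # strictly monotone on distances
        r2 = anosim(dm2, g, n_perm=9, seed=1).R
        assert r1 == pytest.approx(r2)

    def test_errors(self):
        dm = dm_from_points(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(DataError):
            anosim(dm, ["a", "a", "a", "b"])
        with pytest.raises(DataError):
            anosim(dm, ["a"] * 4)


class TestMantel:
    def test_self_correlation_is_one(self):
        dm = dm_from_points(np.random.default_rng(1).normal(size=(7, 2)))
        res = mantel(dm, dm, n_perm=9, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_p_matches_exhaustive_enumeration_n5(self):
        rng = np.random.default_rng(6)
        d1 = dm_from_points(rng.normal(size=(5, 2)))
        d2 = dm_from_points(rng.normal(size=(5, 2)), labels=d1.labels)
        v1 = squareform(d1.values, checks=False)
        r_obs = np.corrcoef(v1, squareform(d2.values, checks=False))[0, 1]
        null = []
        for perm in itertools.permutations(range(5)):
            v2p = squareform(d2.values[np.ix_(perm, perm)], checks=False)
            null.append(np.corrcoef(v1, v2p)[0, 1])
        exact_p = np.mean(np.array(null) >= r_obs - 1e-12)
        res = mantel(d1, d2, n_perm=9999, seed=0)
        # sampled estimate agrees within ~3 binomial standard errors
        se = np.sqrt(exact_p * (1 - exact_p) / 9999)
        assert abs(res.p - exact_p) < 3 * se + 1e-4

    def test_label_mismatch(self):
        d1 = dm_from_points(np.random.default_rng(0).normal(size=(4, 2)))
        d2 = dm_from_points(np.random.default_rng(1).normal(size=(4, 2)),
                            labels=["x0", "x1", "x2", "x3"])
        with pytest.raises(DataError):
            mantel(d1, d2)

    def test_symmetry_of_pearson_r(self):
        rng = np.random.default_rng(7)
        d1 = dm_from_points(rng.normal(size=(8, 2)))
        d2 = dm_from_points(rng.normal(size=(8, 2)), labels=d1.labels)
        assert mantel(d1, d2, n_perm=9, seed=0).r == pytest.approx(
            mantel(d2, d1, n_perm=9, seed=0).r)

    def test_matches_skbio_statistic(self):
        pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(8)
        d1 = dm_from_points(rng.normal(size=(9, 2)))
        d2 = dm_from_points(rng.normal(size=(9, 2)), labels=d1.labels)
        r_ref, _, _ = skbio_mantel(SkbioDM(d1.values, d1.labels),
                                   SkbioDM(d2.values, d2.labels),
                                   method="pearson", permutations=0)
        assert mantel(d1, d2, n_perm=9, seed=0).r == pytest.approx(float(r_ref))


class TestPartialMantel:
    def test_controls_for_itself(self):
        rng = np.random.default_rng(9)
        d1 = dm_from_points(rng.normal(size=(10, 2)))
        d2 = dm_from_points(rng.normal(size=(10, 2)), labels=d1.labels)
        res = partial_mantel(d1, d2, d2, n_perm=9, seed=0)
        assert abs(res.r) < 1e-8

    def test_uncorrelated_control_leaves_r(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(30, 2))
        d1 = dm_from_points(pts)
        d2 = dm_from_points(pts + rng.normal(0, 0.3, size=(30, 2)), labels=d1.labels)
        d3 = dm_from_points(rng.normal(size=(30, 2)), labels=d1.labels)
        plain = mantel(d1, d2, n_perm=9, seed=0).r
        part = partial_mantel(d1, d2, d3, n_perm=9, seed=0).r
        assert abs(plain - part) < 0.05

    def test_label_mismatch(self):
        rng = np.random.default_rng(11)
        d1 = dm_from_points(rng.normal(size=(5, 2)))
        d3 = dm_from_points(rng.normal(size=(5, 2)), labels=["q0", "q1", "q2", "q3", "q4"])
        with pytest.raises(DataError):
            partial_mantel(d1, d1, d3)
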