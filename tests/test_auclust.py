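"""Correlation distance, UPGMA, multiscale bootstrap and AU selection."""

import numpy as np
import pytest
from scipy.special import ndtr, ndtri

from camcr.auclust import (
    ClusterCandidate,
    Dendrogram,
    au_from_bp,
    correlation_distance,
    hclust_average,
    multiscale_bootstrap,
    pv_cluster,
    pvpick,
)


def brute_force_upgma(D):
    """Independent UPGMA oracle: explicit cross-pair averaging over leaf sets."""
    D = np.asarray(D, dtype=float)
    m = D.shape[0]
    clusters = {i: [i] for i in range(m)}
    heights = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ii, a in enumerate(keys):
            for b in keys[ii + 1 :]:
                d = np.mean([D[x, y] for x in clusters[a] for y in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[min(a, b)] = clusters.pop(a) + clusters.pop(b)
    return np.array(heights)


class TestCorrelationDistance:
    def test_identical_and_anticorrelated(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.vstack([x, x, -x])
        D = correlation_distance(X)
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert D[0, 2] == pytest.approx(2.0, abs=1e-12)
        assert np.allclose(np.diag(D), 0)

    def test_matches_pairwise_formula(self, rng):
        X = rng.normal(size=(5, 10))
        D = correlation_distance(X)
        for i in range(5):
            for j in range(5):
                expected = 1 - np.corrcoef(X[i], X[j])[0, 1]
                assert D[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_row_rejected(self):
        X = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="constant"):
            correlation_distance(X, ids=["flat", "ok"])


class TestUPGMA:
    def test_forced_merge_order(self):
        D = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], dtype=float)
        dend = hclust_average(D, ids=["A", "B", "C"])
        np.testing.assert_allclose(dend.heights, [1.0, 4.0])
        sets = dend.node_leaf_sets()
        assert sets[0] == {"A", "B"}
        assert sets[1] == {"A", "B", "C"}

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            m = 6
            P = rng.uniform(0, 1, (m, m))
            D = (P + P.T) / 2
            np.fill_diagonal(D, 0)
            dend = hclust_average(D)
            np.testing.assert_allclose(dend.heights, brute_force_upgma(D), atol=1e-10)

    def test_all_equal_distances_deterministic(self):
        D = np.ones((4, 4)) - np.eye(4)
        a = hclust_average(D).Z
        b = hclust_average(D).Z
        np.testing.assert_array_equal(a, b)

    def test_newick_export(self):
        D = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], dtype=float)
        dend = hclust_average(D, ids=["A", "B", "C"])
        nwk = dend.to_newick()
        assert nwk.endswith(";") and "A" in nwk and "C" in nwk


class TestMultiscaleBootstrap:
    def _two_groups(self, rng, n=18):
        a = rng.uniform(0, 1, n)
        b = rng.uniform(0, 1, n)
        rows = [a + rng.normal(0, 0.01, n) for _ in range(4)] + [
            b + rng.normal(0, 0.01, n) for _ in range(4)
        ]
        return np.vstack(rows)

    def test_tight_groups_high_bp(self, rng):
        X = self._two_groups(rng)
        dend = hclust_average(correlation_distance(X))
        bp = multiscale_bootstrap(X, dend, scales=(0.6, 1.0, 1.4), nboot=200, seed=1)
        sets = dend.node_index_sets()
        g1, g2 = frozenset(range(4)), frozenset(range(4, 8))
        for g in (g1, g2):
            pos = sets.index(g)
            for r in (0.6, 1.0, 1.4):
                assert bp[r][pos] >= 0.95

    def test_nboot_one_gives_binary_bp(self, rng):
        X = rng.normal(size=(6, 12))
        dend = hclust_average(correlation_distance(X))
        bp = multiscale_bootstrap(X, dend, scales=(1.0,), nboot=1, seed=3)
        assert set(np.unique(bp[1.0])) <= {0.0, 1.0}

    def test_scale_too_small_rejected(self, rng):
        X = rng.normal(size=(5, 10))
        dend = hclust_average(correlation_distance(X))
        with pytest.raises(ValueError, match="< 2"):
            multiscale_bootstrap(X, dend, scales=(0.1,), nboot=5, seed=0)

    def test_reproducible_given_seed(self, rng):
        X = rng.normal(size=(7, 15))
        dend = hclust_average(correlation_distance(X))
        a = multiscale_bootstrap(X, dend, scales=(0.8, 1.2), nboot=50, seed=9)
        b = multiscale_bootstrap(X, dend, scales=(0.8, 1.2), nboot=50, seed=9)
        for r in a:
            np.testing.assert_array_equal(a[r], b[r])

    def test_bp_at_scale_one_approximates_plain_bootstrap(self, rng):
        # plain-bootstrap oracle on a 6-row instance: independent resampling
        # loop recomputing trees and counting the same leaf sets
        X = self._two_groups(rng, n=14)[[0, 1, 2, 4, 5, 6]]
        dend = hclust_average(correlation_distance(X))
        bp = multiscale_bootstrap(X, dend, scales=(1.0,), nboot=400, seed=5)
        sets = dend.node_index_sets()
        rng2 = np.random.default_rng(99)
        counts = np.zeros(len(sets))
        for _ in range(400):
            idx = rng2.integers(0, 14, 14)
            Xb = X[:, idx]
            sd = Xb.std(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                Db = 1 - np.corrcoef(Xb)
            Db = np.nan_to_num(Db, nan=2.0)
            np.fill_diagonal(Db, 0)
            bsets = hclust_average((Db + Db.T) / 2).node_index_sets()
            for i, s in enumerate(sets):
                if s in bsets:
                    counts[i] += 1
        plain = counts / 400
        np.testing.assert_allclose(bp[1.0], plain, atol=0.12)


class TestAUFromBP:
    def test_bp_half_everywhere_gives_half(self):
        scales = (0.5, 0.8, 1.0, 1.2, 1.4)
        au, v, c = au_from_bp({r: 0.5 for r in scales}, nboot=1000)
        assert v == pytest.approx(0.0, abs=1e-12)
        assert c == pytest.approx(0.0, abs=1e-12)
        assert au == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("a,b", [(0.5, 0.2), (1.2, -0.3), (-0.4, 0.6)])
    def test_synthesized_curves_recovered(self, a, b):
        # self-consistency oracle: BP generated from the model itself
        scales = tuple(np.arange(0.5, 1.45, 0.1))
        bp = {r: float(ndtr(-(a * np.sqrt(r) + b / np.sqrt(r)))) for r in scales}
        au, v, c = au_from_bp(bp, nboot=10000)
        assert v == pytest.approx(a, abs=0.02)
        assert c == pytest.approx(b, abs=0.02)
        assert au == pytest.approx(1 - ndtr(a - b), abs=0.02)

    def test_all_bp_at_cap_finite_au_near_one(self):
        scales = (0.6, 1.0, 1.4)
        au, v, c = au_from_bp({r: 1.0 for r in scales}, nboot=100)
        assert np.isfinite(au)
        assert au > 0.95

    def test_monotone_in_bp(self):
        scales = (0.6, 1.0, 1.4)
        hi = au_from_bp({r: 0.9 for r in scales}, nboot=1000)[0]
        lo = au_from_bp({r: 0.6 for r in scales}, nboot=1000)[0]
        assert hi > lo

    def test_too_few_scales_rejected(self):
        with pytest.raises(ValueError):
            au_from_bp({1.0: 0.5}, nboot=100)


class TestPvPick:
    def _dend(self, n=5):
        D = np.arange(n * n, dtype=float).reshape(n, n)
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        return hclust_average(D, ids=list("abcde"))

    def _cand(self, dend, aus):
        sets = dend.node_leaf_sets()
        return [
            ClusterCandidate(node=i, leaf_ids=s, au=aus[i]) for i, s in enumerate(sets)
        ]

    def test_nothing_significant(self):
        dend = self._dend()
        picked = pvpick(dendrogram=dend, candidates=self._cand(dend, [0.5] * 4))
        assert picked == []

    def test_nested_prefers_maximal(self, rng):
        X = np.vstack(
            [rng.uniform(0, 1, 10) + rng.normal(0, 0.01, 10) for _ in range(4)]
            + [rng.uniform(0, 1, 10) for _ in range(2)]
        )
        res = pv_cluster(X, nboot=100, seed=0)
        picked = pvpick(res, alpha=0.9)
        for i, a in enumerate(picked):
            for b in picked[i + 1 :]:
                assert not (a & b)  # disjoint
            for cand in res.candidates:
                # no selected set is strictly contained in another significant one
                if cand.au is not None and cand.au > 0.9 and cand.node != len(res.dendrogram.Z) - 1:
                    assert not (a < cand.leaf_ids)

    def test_root_never_selected(self, rng):
        X = rng.normal(size=(6, 10))
        res = pv_cluster(X, nboot=50, seed=2)
        picked = pvpick(res, alpha=0.0)  # everything "significant"
        all_leaves = frozenset(res.dendrogram.ids)
        assert all_leaves not in picked

    def test_two_disjoint_significant(self):
        dend = self._dend()
        sets = dend.node_leaf_sets()
        aus = [0.99 if len(s) == 2 else 0.1 for s in sets]
        picked = pvpick(dendrogram=dend, candidates=self._cand(dend, aus))
        assert len(picked) >= 1
        for i, a in enumerate(picked):
            for b in picked[i + 1 :]:
                assert not (a & b)
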