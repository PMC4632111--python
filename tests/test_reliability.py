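"""Shuffle null, size threshold, and correlation-based refinement."""

import numpy as np
import pytest

from camcr.reliability import (
    SizeThreshold,
    refine_cluster,
    replicate_seeds,
    select_reliable,
    shuffle_clist,
    size_threshold,
    ReliableClusterSet,
)

from conftest import make_clist

SCALES = (0.6, 0.8, 1.0, 1.2)  # reduced scale set keeps unit tests quick


class TestShuffleClist:
    def test_multiset_preserved(self, rng):
        clist = make_clist(rng.uniform(0, 1, (6, 15)))
        out = shuffle_clist(clist, seed=3)
        for a, b in zip(clist.records, out.records):
            np.testing.assert_allclose(
                np.sort(a.concentration), np.sort(b.concentration)
            )

    def test_identical_records_diverge(self, rng):
        row = rng.uniform(0, 1, 30)
        clist = make_clist(np.vstack([row, row]))
        out = shuffle_clist(clist, seed=1)
        a, b = (r.concentration for r in out.records)
        assert not np.array_equal(a, b)

    def test_destroys_planted_correlation(self, planted_clist):
        clist, labels = planted_clist
        X = clist.concentration_matrix()
        Xs = shuffle_clist(clist, seed=9).concentration_matrix()

        def within_group_corr(M):
            vals = []
            for g in range(3):
                R = np.corrcoef(M[labels == g])
                vals.append(R[np.triu_indices_from(R, 1)].mean())
            return np.mean(vals)

        assert within_group_corr(X) > 0.9
        assert within_group_corr(Xs) < within_group_corr(X) / 3

    def test_reproducible(self, rng):
        clist = make_clist(rng.uniform(0, 1, (5, 12)))
        a = shuffle_clist(clist, seed=4).concentration_matrix()
        b = shuffle_clist(clist, seed=4).concentration_matrix()
        np.testing.assert_array_equal(a, b)


class TestSizeThreshold:
    def test_max_rule_and_reproducibility(self, planted_clist):
        clist, _ = planted_clist
        a = size_threshold(clist, n_replicates=3, seed=5, nboot=30, scales=SCALES)
        b = size_threshold(clist, n_replicates=3, seed=5, nboot=30, scales=SCALES)
        assert a.value == max(a.per_replicate_max)
        assert a.per_replicate_max == b.per_replicate_max
        assert len(a.per_replicate_max) == 3

    def test_replicate_seeds_deterministic(self):
        assert replicate_seeds(7, 4) == replicate_seeds(7, 4)
        assert replicate_seeds(7, 4) != replicate_seeds(8, 4)

    def test_n_replicates_positive(self, planted_clist):
        with pytest.raises(ValueError):
            size_threshold(planted_clist[0], n_replicates=0)


class TestRefineCluster:
    def test_coherent_cluster_accepted_unchanged(self, rng):
        base = rng.uniform(0.2, 1.0, 20)
        X = np.vstack([base + rng.normal(0, 0.02, 20) for _ in range(6)])
        clist = make_clist(X)
        cluster = frozenset(clist.ids)
        out = refine_cluster(cluster, clist, threshold=2, nboot=30, scales=SCALES, seed=0)
        assert out == [cluster]

    def test_two_planted_blocks_split(self, rng):
        a = rng.uniform(0.2, 1.0, 24)
        b = rng.uniform(0.2, 1.0, 24)
        X = np.vstack(
            [a + rng.normal(0, 0.03, 24) for _ in range(6)]
            + [b + rng.normal(0, 0.03, 24) for _ in range(6)]
        )
        clist = make_clist(X)
        audit = ReliableClusterSet([], threshold=2)
        out = refine_cluster(
            frozenset(clist.ids), clist, threshold=2, nboot=100, scales=SCALES,
            seed=1, _audit=audit,
        )
        assert len(out) == 2
        sizes = sorted(len(s) for s in out)
        assert sizes == [6, 6]
        ids = clist.ids
        blocks = [frozenset(ids[:6]), frozenset(ids[6:])]
        assert set(out) == set(blocks)

    def test_small_incoherent_cluster_discarded(self, rng):
        X = rng.uniform(0, 1, (3, 15))
        clist = make_clist(X)
        audit = ReliableClusterSet([], threshold=3)
        out = refine_cluster(
            frozenset(clist.ids), clist, threshold=3, nboot=20, scales=SCALES,
            seed=2, _audit=audit,
        )
        assert out == []
        assert audit.rejected and audit.rejected[0][1] == "too_small"


class TestSelectReliable:
    def test_planted_groups_recovered(self, planted_clist):
        clist, labels = planted_clist
        sel = select_reliable(clist, threshold=4, nboot=100, scales=SCALES, seed=3)
        assert len(sel.clusters) == 3
        ids = np.array(clist.ids)
        found = {frozenset(ids[labels == g]) for g in range(3)}
        assert set(sel.clusters) == found

    def test_invariants_hold(self, planted_clist):
        clist, _ = planted_clist
        sel = select_reliable(clist, threshold=4, nboot=100, scales=SCALES, seed=3)
        X = clist.concentration_matrix()
        idx = {rid: i for i, rid in enumerate(clist.ids)}
        for i, a in enumerate(sel.clusters):
            assert len(a) > 4
            rows = X[[idx[r] for r in sorted(a)]]
            R = np.corrcoef(rows)
            assert R[np.triu_indices_from(R, 1)].min() > 0.6
            for b in sel.clusters[i + 1 :]:
                assert not (a & b)

    def test_threshold_larger_than_everything(self, planted_clist):
        clist, _ = planted_clist
        sel = select_reliable(clist, threshold=1000, nboot=30, scales=SCALES, seed=1)
        assert sel.clusters == []

    def test_corr_min_disabled(self, planted_clist):
        # corr_min = -1 -> refinement never triggers; output is pvpick
        # survivors above the size threshold
        clist, _ = planted_clist
        sel = select_reliable(
            clist, corr_min=-1.0, threshold=4, nboot=100, scales=SCALES, seed=3
        )
        assert sel.splits == []
        assert all(len(c) > 4 for c in sel.clusters)

    def test_null_self_consistency(self, planted_clist):
        # the threshold's own null: applying the pipeline to a shuffled CList
        # with matched seeds yields zero reliable clusters
        clist, _ = planted_clist
        thr = size_threshold(clist, n_replicates=3, seed=11, nboot=60, scales=SCALES)
        shuf_seed, boot_seed = replicate_seeds(11, 3)[0]
        shuffled = shuffle_clist(clist, shuf_seed)
        sel = select_reliable(
            shuffled, threshold=thr, nboot=60, scales=SCALES, seed=boot_seed
        )
        assert sel.clusters == []
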