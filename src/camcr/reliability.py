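"""Reliable-cluster selection: randomized size threshold and refinement.

A selected cluster is only trusted when (a) it is larger than any cluster
that arises from data whose correlation structure has been destroyed by
shuffling, and (b) its members really do share one concentration pattern
(minimum pairwise Pearson correlation above a cutoff, default 0.6).
Clusters failing (b) are re-clustered recursively on their members alone;
fragments that fall to or below the size threshold are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .auclust import DEFAULT_SCALES, pv_cluster, pvpick
from .sweep import CList

__all__ = [
    "SizeThreshold",
    "ReliableClusterSet",
    "shuffle_clist",
    "size_threshold",
    "refine_cluster",
    "select_reliable",
    "replicate_seeds",
]


@dataclass
class SizeThreshold:
    """Largest chance-cluster size over shuffled-data replicates."""

    value: int
    per_replicate_max: list[int]
    n_replicates: int
    seed: int


@dataclass
class ReliableClusterSet:
    """Accepted clusters plus an audit trail of rejections and splits."""

    clusters: list[frozenset[str]]
    rejected: list[tuple[frozenset[str], str]] = field(default_factory=list)
    splits: list[tuple[frozenset[str], list[frozenset[str]]]] = field(default_factory=list)
    threshold: int = 0
    alpha: float = 0.95
    corr_min: float = 0.6


def replicate_seeds(seed: int, n: int) -> list[tuple[int, int]]:
    """Deterministic (shuffle_seed, bootstrap_seed) pairs per replicate.

    Exposed so a shuffled replicate can be reproduced exactly outside
    :func:`size_threshold` (e.g. for null self-consistency checks).
    """
    children = np.random.SeedSequence(seed).spawn(n)
    out = []
    for child in children:
        a, b = child.generate_state(2)
        out.append((int(a % (2**31)), int(b % (2**31))))
    return out


def shuffle_clist(clist: CList, seed: int) -> CList:
    """Independently permute each record's values across sample positions.

    Destroys the correlation structure between profiles (the clustering
    signal) while preserving each profile's value multiset.
    """
    if len(clist) < 2:
        raise ValueError("need at least 2 records")
    rng = np.random.default_rng(seed)
    recs = []
    for r in clist.records:
        perm = rng.permutation(len(r.concentration))
        recs.append(type(r)(r.run_k, r.index_in_run, r.concentration[perm], r.spectrum))
    return CList(recs, clist.n_samples, clist.n_bins, dict(clist.provenance))


def size_threshold(
    clist: CList,
    n_replicates: int = 10,
    alpha: float = 0.95,
    seed: int = 0,
    nboot: int = 1000,
    scales: tuple[float, ...] = DEFAULT_SCALES,
) -> SizeThreshold:
    """Max selected-cluster size over shuffled replicates.

    Each replicate shuffles the CList, clusters it with AU p-values, picks
    significant clusters and records the largest size (0 when nothing is
    selected).  The reliability test downstream requires size strictly
    greater than the returned maximum.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    maxima = []
    for shuf_seed, boot_seed in replicate_seeds(seed, n_replicates):
        shuffled = shuffle_clist(clist, shuf_seed)
        res = pv_cluster(
            shuffled.concentration_matrix(),
            ids=shuffled.ids,
            scales=scales,
            nboot=nboot,
            seed=boot_seed,
        )
        picked = pvpick(res, alpha=alpha)
        maxima.append(max((len(s) for s in picked), default=0))
    return SizeThreshold(
        value=max(maxima),
        per_replicate_max=maxima,
        n_replicates=n_replicates,
        seed=seed,
    )


def _min_pairwise_corr(X: np.ndarray) -> float:
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    R = np.nan_to_num(R, nan=-1.0)
    iu = np.triu_indices_from(R, 1)
    return float(R[iu].min())


def refine_cluster(
    cluster: frozenset[str],
    clist: CList,
    corr_min: float = 0.6,
    threshold: int = 0,
    alpha: float = 0.95,
    nboot: int = 1000,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    seed: int = 0,
    _audit: ReliableClusterSet | None = None,
) -> list[frozenset[str]]:
    """Recursively divide a cluster until its members are mutually correlated.

    Accept as-is when min pairwise correlation > corr_min and size >
    threshold; otherwise recluster the members alone (same average-linkage /
    correlation-distance engine) and divide at the top split of the
    resulting dendrogram, re-checking each part.  Parts at or below the size
    threshold are discarded.  Each division strictly shrinks the cluster, so
    the recursion terminates.  The division is deterministic — no bootstrap
    enters the refinement loop, only the initial cluster selection.

    ``alpha``, ``nboot``, ``scales`` and ``seed`` are accepted for interface
    symmetry with :func:`select_reliable` but the refinement itself draws no
    random numbers.
    """
    audit = _audit if _audit is not None else ReliableClusterSet([], threshold=threshold)
    if len(cluster) <= threshold:
        audit.rejected.append((cluster, "too_small"))
        return []
    members = sorted(cluster)
    sub = clist.subset(members)
    X = sub.concentration_matrix()
    if _min_pairwise_corr(X) > corr_min:
        audit.clusters.append(cluster)
        return [cluster]
    if len(cluster) == 2:
        # an incoherent pair cannot be divided into clusters
        audit.rejected.append((cluster, "low_correlation_unresolvable"))
        return []
    from .auclust import _distance_with_degenerate, hclust_average

    dend = hclust_average(_distance_with_degenerate(X), ids=sub.ids)
    leaf_sets = dend.node_leaf_sets()
    # children of the root: the last merge joins these two subtrees
    a, b = (int(x) for x in dend.Z[-1, :2])
    m = len(members)
    parts = []
    for child in (a, b):
        if child < m:
            parts.append(frozenset([dend.ids[child]]))
        else:
            parts.append(leaf_sets[child - m])
    audit.splits.append((cluster, parts))
    out: list[frozenset[str]] = []
    for part in parts:
        if len(part) == 1:  # singletons are never clusters
            audit.rejected.append((part, "too_small"))
            continue
        out.extend(
            refine_cluster(
                part,
                clist,
                corr_min=corr_min,
                threshold=threshold,
                alpha=alpha,
                nboot=nboot,
                scales=scales,
                seed=seed,
                _audit=audit,
            )
        )
    return out


def select_reliable(
    clist: CList,
    alpha: float = 0.95,
    corr_min: float = 0.6,
    threshold: int | SizeThreshold = 0,
    nboot: int = 1000,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    seed: int = 0,
) -> ReliableClusterSet:
    """Full selection pipeline: cluster → pick → size filter → refine."""
    thr = threshold.value if isinstance(threshold, SizeThreshold) else int(threshold)
    res = pv_cluster(
        clist.concentration_matrix(),
        ids=clist.ids,
        scales=scales,
        nboot=nboot,
        seed=seed,
    )
    picked = pvpick(res, alpha=alpha)
    audit = ReliableClusterSet([], threshold=thr, alpha=alpha, corr_min=corr_min)
    for i, cluster in enumerate(sorted(picked, key=lambda s: (-len(s), sorted(s)))):
        if len(cluster) <= thr:
            audit.rejected.append((cluster, "too_small"))
            continue
        refine_cluster(
            cluster,
            clist,
            corr_min=corr_min,
            threshold=thr,
            alpha=alpha,
            nboot=nboot,
            scales=scales,
            seed=seed + 1000 + i,
            _audit=audit,
        )
    return audit
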