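"""Hierarchical clustering with multiscale-bootstrap AU p-values.

Concentration profiles (records × samples) are clustered with average
linkage (UPGMA) on the correlation distance 1 − r.  Cluster uncertainty is
assessed by the multiscale bootstrap: the sample axis is resampled with
replacement at several relative sizes r, each resample is reclustered, and
the per-scale bootstrap probability BP_r of a node is the fraction of
bootstrap trees containing its exact leaf set.  Transforming to normal
quantiles z_r = Φ⁻¹(1 − BP_r) and fitting z_r ≈ v·√r + c/√r by weighted
least squares yields the approximately unbiased p-value
AU = 1 − Φ(v − c), which corrects the ordinary bootstrap probability's bias
from the curvature of the cluster-region boundary.  Significant
(AU > alpha), maximal, non-nested clusters are then picked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.special import ndtr, ndtri

__all__ = [
    "Dendrogram",
    "ClusterCandidate",
    "PvClustResult",
    "DEFAULT_SCALES",
    "correlation_distance",
    "hclust_average",
    "multiscale_bootstrap",
    "au_from_bp",
    "pvpick",
    "pv_cluster",
]

#: default relative bootstrap sample sizes (ten scales around 1)
DEFAULT_SCALES: tuple[float, ...] = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))


def correlation_distance(X: np.ndarray, ids: list[str] | None = None) -> np.ndarray:
    """Pairwise 1 − Pearson r between rows; rejects constant rows."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 records")
    sd = X.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        labels = [ids[i] if ids else str(i) for i in bad]
        raise ValueError(f"constant records have undefined correlation: {labels}")
    D = 1.0 - np.corrcoef(X)
    np.clip(D, 0.0, 2.0, out=D)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def _distance_with_degenerate(X: np.ndarray) -> np.ndarray:
    """Correlation distance assigning the maximum (2) to constant rows.

    Used inside bootstrap replicates, where resampling the sample axis can
    make a profile constant.
    """
    sd = X.std(axis=1)
    const = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    D = 1.0 - R
    D[np.isnan(D)] = 2.0
    if const.any():
        D[const, :] = 2.0
        D[:, const] = 2.0
    np.clip(D, 0.0, 2.0, out=D)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


@dataclass
class Dendrogram:
    """UPGMA merge history over a fixed set of leaves."""

    Z: np.ndarray  # scipy linkage matrix
    ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]

    def node_index_sets(self) -> list[frozenset[int]]:
        """Leaf-index set of every internal node, in merge order."""
        m = self.n_leaves
        members: list[frozenset[int]] = [frozenset([i]) for i in range(m)]
        out = []
        for a, b in self.Z[:, :2].astype(int):
            s = members[a] | members[b]
            members.append(s)
            out.append(s)
        return out

    def node_leaf_sets(self) -> list[frozenset[str]]:
        """Leaf-id set of every internal node, in merge order."""
        return [
            frozenset(self.ids[i] for i in s) for s in self.node_index_sets()
        ]

    def to_newick(self, node_labels: list[str] | None = None) -> str:
        m = self.n_leaves
        names: list[str] = [str(i) for i in range(2 * m - 1)]
        for i, leaf in enumerate(self.ids):
            names[i] = leaf
        heights = np.concatenate([np.zeros(m), self.Z[:, 2]])
        for j, (a, b, h, _) in enumerate(self.Z):
            a, b = int(a), int(b)
            la = max(h - heights[a], 0.0) / 2
            lb = max(h - heights[b], 0.0) / 2
            label = node_labels[j] if node_labels else ""
            names[m + j] = f"({names[a]}:{la:g},{names[b]}:{lb:g}){label}"
        return names[-1] + ";"


def hclust_average(dist: np.ndarray, ids: list[str] | None = None) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a square distance matrix."""
    dist = np.asarray(dist, dtype=float)
    m = dist.shape[0]
    if ids is None:
        ids = [str(i) for i in range(m)]
    Z = linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(Z=Z, ids=list(ids))


def _tree_cluster_sets(Z: np.ndarray, m: int, skip_root: bool = True) -> list[frozenset[int]]:
    members: list[frozenset[int]] = [frozenset([i]) for i in range(m)]
    out = []
    last = len(Z) - 1
    for j, (a, b) in enumerate(Z[:, :2].astype(int)):
        s = members[a] | members[b]
        members.append(s)
        if not (skip_root and j == last):
            out.append(s)
    return out


def multiscale_bootstrap(
    X: np.ndarray,
    dendrogram: Dendrogram,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    nboot: int = 1000,
    seed: int = 0,
) -> dict[float, np.ndarray]:
    """Per-scale bootstrap probabilities for every internal node.

    At scale r, nboot resamples of round(n_samples · r) sample-columns
    (with replacement) are drawn, each reclustered with the same distance
    and linkage, and BP_r(node) is the fraction of bootstrap trees that
    contain the node's exact leaf set.  Scales where the resample would have
    fewer than 2 columns are rejected.
    """
    X = np.asarray(X, dtype=float)
    if nboot < 1:
        raise ValueError("nboot must be >= 1")
    n = X.shape[1]
    m = X.shape[0]
    node_sets = dendrogram.node_index_sets()
    set_to_pos = {s: i for i, s in enumerate(node_sets)}
    rng = np.random.default_rng(seed)
    bp: dict[float, np.ndarray] = {}
    for r in scales:
        if r <= 0:
            raise ValueError("scales must be positive")
        n_prime = int(round(n * r))
        if n_prime < 2:
            raise ValueError(f"scale {r} gives a bootstrap sample of size {n_prime} < 2")
        counts = np.zeros(m - 1)
        for _ in range(nboot):
            idx = rng.integers(0, n, size=n_prime)
            Db = _distance_with_degenerate(X[:, idx])
            Zb = linkage(squareform(Db, checks=False), method="average")
            for s in _tree_cluster_sets(Zb, m, skip_root=False):
                pos = set_to_pos.get(s)
                if pos is not None:
                    counts[pos] += 1
        bp[float(r)] = counts / nboot
    return bp


def au_from_bp(
    bp: dict[float, float], nboot: int | dict[float, int]
) -> tuple[float, float, float]:
    """Fit the multiscale model and return (AU, v, c).

    BP values are capped into [1/(B+1), B/(B+1)], transformed to
    z_r = Φ⁻¹(1 − BP_r), and z_r ≈ v√r + c/√r is fitted by least squares
    weighted by the (delta-method) binomial variance of z_r.  AU is
    1 − Φ(v − c).

    A node found in every bootstrap tree at every scale (or in none) gives
    the fit no scale information: AU degenerates to 1 (or 0) directly.
    Partially censored scales enter the fit at their capped values, which
    anchors the curve and keeps near-zero-BP nodes from extrapolating to
    spuriously high AU through the curvature term.
    """
    scales = sorted(bp)
    if len(scales) < 2:
        raise ValueError("need BP at >= 2 scales")
    raw = np.array([bp[r] for r in scales])
    if np.all(raw >= 1.0):
        return 1.0, 0.0, 0.0
    if np.all(raw <= 0.0):
        return 0.0, 0.0, 0.0
    if not isinstance(nboot, dict):
        nboot = {r: int(nboot) for r in scales}
    z, w, sq = [], [], []
    for r in scales:
        B = nboot[r]
        p = min(max(bp[r], 1.0 / (B + 1)), B / (B + 1.0))
        zr = ndtri(1.0 - p)
        phi = np.exp(-0.5 * zr**2) / np.sqrt(2 * np.pi)
        var = p * (1 - p) / (B * phi**2)
        z.append(zr)
        w.append(1.0 / var)
        sq.append(np.sqrt(r))
    z = np.asarray(z)
    w = np.asarray(w)
    sq = np.asarray(sq)
    A = np.column_stack([sq, 1.0 / sq])
    Aw = A * w[:, None]
    try:
        beta = np.linalg.solve(A.T @ Aw, Aw.T @ z)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(A * np.sqrt(w)[:, None], z * np.sqrt(w), rcond=None)[0]
    v, c = float(beta[0]), float(beta[1])
    au = float(1.0 - ndtr(v - c))
    return au, v, c


@dataclass
class ClusterCandidate:
    """An internal dendrogram node with its bootstrap support."""

    node: int  # merge index in the linkage matrix
    leaf_ids: frozenset[str]
    bp: dict[float, float] = field(default_factory=dict)
    au: float | None = None
    v: float = 0.0
    c: float = 0.0


@dataclass
class PvClustResult:
    """Dendrogram plus AU/BP support for every internal node."""

    dendrogram: Dendrogram
    candidates: list[ClusterCandidate]
    nboot: int
    scales: tuple[float, ...]
    seed: int

    def report(self) -> pd.DataFrame:
        rows = []
        for cand in self.candidates:
            row = {
                "node": cand.node,
                "size": len(cand.leaf_ids),
                "au": cand.au,
                "v": cand.v,
                "c": cand.c,
            }
            for r, p in cand.bp.items():
                row[f"bp_{r:g}"] = p
            rows.append(row)
        return pd.DataFrame(rows)

    def to_newick(self) -> str:
        labels = [
            "" if cand.au is None else f"{cand.au:.3f}" for cand in self.candidates
        ]
        return self.dendrogram.to_newick(labels)


def pv_cluster(
    X: np.ndarray,
    ids: list[str] | None = None,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    nboot: int = 1000,
    seed: int = 0,
) -> PvClustResult:
    """Cluster records × samples data and attach AU p-values to every node."""
    X = np.asarray(X, dtype=float)
    if ids is None:
        ids = [str(i) for i in range(X.shape[0])]
    dist = _distance_with_degenerate(X)
    dend = hclust_average(dist, ids)
    bp = multiscale_bootstrap(X, dend, scales=scales, nboot=nboot, seed=seed)
    leaf_sets = dend.node_leaf_sets()
    candidates = []
    for j, leaves in enumerate(leaf_sets):
        node_bp = {r: float(bp[r][j]) for r in bp}
        au, v, c = au_from_bp(node_bp, nboot)
        candidates.append(
            ClusterCandidate(node=j, leaf_ids=leaves, bp=node_bp, au=au, v=v, c=c)
        )
    return PvClustResult(dend, candidates, nboot, tuple(scales), seed)


def pvpick(
    result: PvClustResult | None = None,
    alpha: float = 0.95,
    max_only: bool = True,
    dendrogram: Dendrogram | None = None,
    candidates: list[ClusterCandidate] | None = None,
) -> list[frozenset[str]]:
    """Select significant clusters (AU > alpha), keeping only maximal ones.

    The root node is never a candidate (its BP is 1 by construction at every
    scale), and singletons are never returned.  Because dendrogram node sets
    are laminar, keeping maximal significant nodes yields pairwise disjoint
    clusters.
    """
    if result is not None:
        dendrogram = result.dendrogram
        candidates = result.candidates
    assert dendrogram is not None and candidates is not None
    root = len(dendrogram.Z) - 1
    selected = [
        cand
        for cand in candidates
        if cand.node != root and cand.au is not None and cand.au > alpha
        and len(cand.leaf_ids) >= 2
    ]
    if not max_only:
        return [cand.leaf_ids for cand in selected]
    selected.sort(key=lambda cand: -len(cand.leaf_ids))
    kept: list[frozenset[str]] = []
    for cand in selected:
        if not any(cand.leaf_ids <= big for big in kept):
            kept.append(cand.leaf_ids)
    return kept
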