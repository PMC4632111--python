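"""Cluster summaries: C×Sᵗ stacks, typical profiles, SSD, detection scoring.

Clusters are formed from concentration information only; to re-attach the
spectral information, each member's rank-one matrix C×Sᵗ (outer product of
its concentration and spectral profile) is stacked and summarized
element-wise (mean, SD, CV).  The row and column of the mean matrix through
its global maximum serve as the cluster's typical spectral and
concentration profile, the sum of squared deviations of the typical
concentration profile ranks clusters by information content, and a known
concentration table scores per-compound detection (Pearson r > 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcr import ComponentRecord
from .sweep import CList
from .synth import ConcentrationDesign

__all__ = [
    "ReliableCluster",
    "member_product",
    "cluster_stats",
    "typical_profiles",
    "cluster_ssd",
    "summarize_cluster",
    "summarize_clusters",
    "detection_score",
]


def member_product(record: ComponentRecord) -> np.ndarray:
    """Rank-one samples × bins matrix: concentration ⊗ spectrum."""
    return np.outer(record.concentration, record.spectrum)


def cluster_stats(
    members: list[ComponentRecord],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Element-wise mean, sample SD (n−1) and CV across the member stack.

    A single-member stack has SD 0 everywhere; CV is defined as 0 where the
    mean is 0 (cells that carry none of the cluster's signal).
    """
    if not members:
        raise ValueError("cluster must have at least one member")
    stack = np.stack([member_product(r) for r in members])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(members) > 1 else np.zeros_like(mean)
    cv = np.divide(sd, mean, out=np.zeros_like(sd), where=mean > 0)
    return mean, sd, cv


def typical_profiles(mean_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(typical_spectrum, typical_concentration) through the global maximum.

    The row (across bins) and column (across samples) of the mean C×Sᵗ
    matrix containing its maximum entry; ties break at the first occurrence
    in row-major order.
    """
    M = np.asarray(mean_matrix, dtype=float)
    if not (M > 0).any():
        raise ValueError("mean matrix has no positive entry")
    r, c = np.unravel_index(np.argmax(M), M.shape)
    return M[r, :].copy(), M[:, c].copy()


def cluster_ssd(profile: np.ndarray) -> float:
    """Sum of squared deviations Σ(xᵢ − x̄)² of a profile."""
    x = np.asarray(profile, dtype=float)
    return float(((x - x.mean()) ** 2).sum())


@dataclass
class ReliableCluster:
    """An accepted cluster with its element-wise summary."""

    cluster_id: str
    members: list[ComponentRecord]
    mean_matrix: np.ndarray
    sd_matrix: np.ndarray
    cv_matrix: np.ndarray
    typical_concentration: np.ndarray
    typical_spectrum: np.ndarray
    ssd: float

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def member_ids(self) -> list[str]:
        return [r.id for r in self.members]


def summarize_cluster(
    cluster_id: str, member_ids: list[str] | frozenset[str], clist: CList
) -> ReliableCluster:
    by_id = clist.by_id()
    members = [by_id[i] for i in sorted(member_ids)]
    mean, sd, cv = cluster_stats(members)
    spec, conc = typical_profiles(mean)
    return ReliableCluster(
        cluster_id=cluster_id,
        members=members,
        mean_matrix=mean,
        sd_matrix=sd,
        cv_matrix=cv,
        typical_concentration=conc,
        typical_spectrum=spec,
        ssd=cluster_ssd(conc),
    )


def summarize_clusters(
    clusters: list[frozenset[str]], clist: CList
) -> list[ReliableCluster]:
    """Summarize clusters, numbering them in decreasing SSD (information) order."""
    out = [
        summarize_cluster(f"tmp{i}", members, clist)
        for i, members in enumerate(clusters)
    ]
    out.sort(key=lambda cl: -cl.ssd)
    for i, cl in enumerate(out):
        cl.cluster_id = f"cluster_{i + 1}"
    return out


def summary_table(clusters: list[ReliableCluster], bin_centers=None) -> pd.DataFrame:
    rows = []
    for cl in clusters:
        top = np.argsort(cl.typical_spectrum)[::-1][:3]
        if bin_centers is not None:
            top_lbl = ", ".join(f"{bin_centers[i]:g}" for i in top)
        else:
            top_lbl = ", ".join(str(int(i)) for i in top)
        rows.append(
            {
                "cluster_id": cl.cluster_id,
                "size": cl.size,
                "ssd": cl.ssd,
                "top_bins": top_lbl,
            }
        )
    return pd.DataFrame(rows)


def detection_score(
    clusters: list[ReliableCluster],
    known: ConcentrationDesign,
    detect_r: float = 0.8,
) -> pd.DataFrame:
    """Best cluster match per known compound; detected iff Pearson r > 0.8.

    One cluster may be the best match for several compounds (concentration-
    confounded compounds resolve into a shared cluster).  Compounds with a
    constant concentration series have undefined correlation and are
    reported as missing.
    """
    rows = []
    for j, name in enumerate(known.compound_names):
        series = known.matrix[:, j]
        if np.std(series) == 0:
            rows.append(
                {"compound": name, "best_cluster": None, "best_correlation": np.nan,
                 "detected": False}
            )
            continue
        best_r, best_cl = -np.inf, None
        for cl in clusters:
            prof = cl.typical_concentration
            if np.std(prof) == 0:
                continue
            r = float(np.corrcoef(series, prof)[0, 1])
            if r > best_r:
                best_r, best_cl = r, cl.cluster_id
        if best_cl is None:
            best_r = np.nan
        rows.append(
            {
                "compound": name,
                "best_cluster": best_cl,
                "best_correlation": best_r,
                "detected": bool(best_r > detect_r) if np.isfinite(best_r) else False,
            }
        )
    return pd.DataFrame(rows)
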