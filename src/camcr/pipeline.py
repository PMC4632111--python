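"""End-to-end workflows: the cluster-aided model object and the conventional baseline.

`ClusterAidedMCR` is the model-level entry point: given a non-negative
samples × bins matrix it sweeps MCR-ALS over all component numbers, pools
the concentration profiles, clusters them with AU p-values, derives the
shuffled-data size threshold, refines by internal correlation and
summarizes each reliable cluster.  `run_conventional` is the comparison
baseline: estimate one component number (parallel analysis by default) and
run a single MCR-ALS fit at it.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ncomp
from .auclust import DEFAULT_SCALES, pv_cluster, pvpick
from .mcr import MCRALS
from .preprocess import BinnedMatrix, bin_spectra, exclude_regions, normalize_total, read_long_csv
from .reliability import ReliableClusterSet, SizeThreshold, select_reliable, size_threshold
from .summarize import ReliableCluster, detection_score, summarize_clusters, summary_table
from .sweep import CList, run_sweep

__all__ = [
    "ClusterAidedMCR",
    "ClusterAidedMCRResults",
    "RunConfig",
    "run_pipeline",
    "run_conventional",
]


class ClusterAidedMCR:
    """Cluster-aided MCR-ALS model for a non-negative data matrix.

    Parameters
    ----------
    data : BinnedMatrix or array-like
        Samples × bins non-negative matrix (binned spectra).
    kmax : int, optional
        Largest component number of the sweep; defaults to the number of
        samples.
    alpha : float
        AU p-value threshold for cluster selection (default 0.95).
    corr_min : float
        Minimum internal pairwise correlation of an accepted cluster
        (default 0.6).
    nboot : int
        Bootstrap replicates per scale (default 1000).
    n_shuffle : int
        Shuffled-data replicates for the size threshold (default 10).
    scales : tuple of float
        Relative bootstrap sample sizes.
    """

    def __init__(
        self,
        data,
        kmax: int | None = None,
        alpha: float = 0.95,
        corr_min: float = 0.6,
        nboot: int = 1000,
        n_shuffle: int = 10,
        scales: tuple[float, ...] = DEFAULT_SCALES,
        als_tol: float = 1e-8,
        als_max_iter: int = 200,
    ):
        self.data = data if isinstance(data, BinnedMatrix) else BinnedMatrix(
            np.asarray(data, dtype=float),
            np.arange(np.asarray(data).shape[1], dtype=float),
        )
        self.kmax = kmax
        self.alpha = alpha
        self.corr_min = corr_min
        self.nboot = nboot
        self.n_shuffle = n_shuffle
        self.scales = tuple(scales)
        self.als_tol = als_tol
        self.als_max_iter = als_max_iter

    def fit(self, seed: int = 0, clist: CList | None = None) -> "ClusterAidedMCRResults":
        t0 = time.time()
        if clist is None:
            clist = run_sweep(
                self.data,
                kmax=self.kmax,
                tol=self.als_tol,
                max_iter=self.als_max_iter,
            )
        thr = size_threshold(
            clist,
            n_replicates=self.n_shuffle,
            alpha=self.alpha,
            seed=seed,
            nboot=self.nboot,
            scales=self.scales,
        )
        selection = select_reliable(
            clist,
            alpha=self.alpha,
            corr_min=self.corr_min,
            threshold=thr,
            nboot=self.nboot,
            scales=self.scales,
            seed=seed + 1,
        )
        clusters = summarize_clusters(selection.clusters, clist)
        return ClusterAidedMCRResults(
            model=self,
            clist=clist,
            threshold=thr,
            selection=selection,
            clusters=clusters,
            seed=seed,
            elapsed=time.time() - t0,
        )


@dataclass
class ClusterAidedMCRResults:
    """Reliable clusters plus everything needed to audit how they were found."""

    model: ClusterAidedMCR
    clist: CList
    threshold: SizeThreshold
    selection: ReliableClusterSet
    clusters: list[ReliableCluster]
    seed: int
    elapsed: float = 0.0

    @property
    def n_reliable(self) -> int:
        return len(self.clusters)

    def summary(self) -> str:
        m = self.model
        tbl = summary_table(self.clusters, self.model.data.bin_centers)
        lines = [
            "Cluster-aided MCR-ALS results",
            "=" * 46,
            f"samples x bins        : {m.data.n_samples} x {m.data.n_bins}",
            f"sweep kmax            : {self.clist.provenance.get('kmax')}",
            f"pooled components     : {len(self.clist)}"
            f" (raw {self.clist.provenance.get('raw_count')})",
            f"AU threshold          : {m.alpha}",
            f"size threshold        : >{self.threshold.value}"
            f" (replicate maxima {self.threshold.per_replicate_max})",
            f"min internal corr     : {m.corr_min}",
            f"reliable clusters     : {self.n_reliable}",
            "",
            tbl.to_string(index=False) if len(tbl) else "(no reliable clusters)",
        ]
        return "\n".join(lines)

    def detection_score(self, known, detect_r: float = 0.8) -> pd.DataFrame:
        return detection_score(self.clusters, known, detect_r=detect_r)

    def membership_frame(self) -> pd.DataFrame:
        rows = []
        for cl in self.clusters:
            for rec in cl.members:
                rows.append(
                    {
                        "cluster_id": cl.cluster_id,
                        "record_id": rec.id,
                        "run_k": rec.run_k,
                        "index_in_run": rec.index_in_run,
                    }
                )
        return pd.DataFrame(rows, columns=["cluster_id", "record_id", "run_k", "index_in_run"])

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.membership_frame().to_csv(outdir / "reliable_clusters.csv", index=False)
        summary_table(self.clusters, self.model.data.bin_centers).to_csv(
            outdir / "cluster_summary.csv", index=False
        )
        samples = self.model.data.sample_ids
        bins = [f"{c:g}" for c in self.model.data.bin_centers]
        for cl in self.clusters:
            d = outdir / cl.cluster_id
            d.mkdir(exist_ok=True)
            pd.Series(cl.typical_concentration, index=samples, name="typical_concentration").to_csv(
                d / "typical_concentration.csv"
            )
            pd.Series(cl.typical_spectrum, index=bins, name="typical_spectrum").to_csv(
                d / "typical_spectrum.csv"
            )
            r, c = np.unravel_index(np.argmax(cl.mean_matrix), cl.mean_matrix.shape)
            pd.Series(cl.cv_matrix[:, c], index=samples, name="cv_concentration").to_csv(
                d / "cv_concentration.csv"
            )
            pd.Series(cl.member_ids, name="record_id").to_csv(d / "members.csv", index=False)


@dataclass
class RunConfig:
    """Serializable description of a full pipeline run."""

    input_path: str | None = None
    output_dir: str = "camcr_out"
    # preprocessing
    bin_width: float | None = None
    ppm_range: tuple[float, float] = (0.0, 10.0)
    exclude: list[tuple[float, float]] = field(default_factory=list)
    normalize: bool = True
    # sweep
    kmax: int | None = None
    als_tol: float = 1e-8
    als_max_iter: int = 200
    # clustering
    alpha: float = 0.95
    corr_min: float = 0.6
    nboot: int = 1000
    n_shuffle: int = 10
    scales: list[float] = field(default_factory=lambda: list(DEFAULT_SCALES))
    # seeds
    seed: int = 0
    # baseline
    ncomp_method: str = "parallel_analysis"
    k_override: int | None = None

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["ppm_range"] = list(self.ppm_range)
        raw["exclude"] = [list(x) for x in self.exclude]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.ppm_range = tuple(cfg.ppm_range)
        cfg.exclude = [tuple(x) for x in cfg.exclude]
        return cfg


def _load_matrix(config: RunConfig) -> BinnedMatrix:
    if config.input_path is None:
        raise ValueError("config.input_path is not set")
    path = Path(config.input_path)
    if not path.exists():
        raise FileNotFoundError(f"input not found: {path}")
    if config.bin_width is not None:
        spectra = read_long_csv(path)
        bm = bin_spectra(spectra, config.bin_width, config.ppm_range)
    else:
        bm = BinnedMatrix.read_csv(path)
    if config.exclude:
        bm = exclude_regions(bm, config.exclude)
    if config.normalize:
        bm = normalize_total(bm)
    return bm


def _provenance(config: RunConfig, extra: dict) -> dict:
    import camcr

    return {
        "config": asdict(config),
        "version": camcr.__version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        **extra,
    }


def run_pipeline(config: RunConfig, data: BinnedMatrix | None = None) -> Path:
    """Execute preprocess → sweep → cluster → refine → summarize, writing artifacts."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bm = data if data is not None else _load_matrix(config)
    bm.to_csv(outdir / "matrix.csv")
    model = ClusterAidedMCR(
        bm,
        kmax=config.kmax,
        alpha=config.alpha,
        corr_min=config.corr_min,
        nboot=config.nboot,
        n_shuffle=config.n_shuffle,
        scales=tuple(config.scales),
        als_tol=config.als_tol,
        als_max_iter=config.als_max_iter,
    )
    res = model.fit(seed=config.seed)
    res.clist.to_csv(outdir / "clist_concentrations.csv", outdir / "clist_spectra.csv")
    res.save(outdir)
    prov = _provenance(
        config,
        {
            "stage_counts": {
                "pooled_records": len(res.clist),
                "raw_records": res.clist.provenance.get("raw_count"),
                "size_threshold": res.threshold.value,
                "threshold_replicates": res.threshold.per_replicate_max,
                "selected_initial": len(res.selection.clusters)
                + len(res.selection.rejected),
                "reliable": res.n_reliable,
            },
            "elapsed_s": res.elapsed,
            "reduced_precision": config.nboot < 1000,
        },
    )
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, default=str)
    with open(outdir / "summary.txt", "w") as fh:
        fh.write(res.summary() + "\n")
    return outdir


def run_conventional(config: RunConfig, data: BinnedMatrix | None = None) -> Path:
    """Baseline: pick one component number, run a single MCR-ALS fit."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bm = data if data is not None else _load_matrix(config)
    if config.k_override is not None:
        k = int(config.k_override)
        method = "override"
    else:
        method = config.ncomp_method
        if method == "parallel_analysis":
            k = ncomp.parallel_analysis(bm, seed=config.seed)
        elif method == "cv_gcv":
            k = ncomp.cv_gcv(bm)
        elif method == "cv_smooth":
            k = ncomp.cv_smooth(bm)
        elif method == "kaiser":
            k = ncomp.kaiser(ncomp.eig_spectrum(bm, standardize=True))
        elif method == "cum_contribution":
            k = ncomp.cum_contribution(ncomp.eig_spectrum(bm))
        else:
            raise ValueError(f"unknown ncomp method {method!r}")
        k = max(k, 1)
    res = MCRALS(bm, k).fit(tol=config.als_tol, max_iter=config.als_max_iter)
    cdf, sdf = res.profiles_frame(
        bin_centers=[f"{c:g}" for c in bm.bin_centers], sample_ids=bm.sample_ids
    )
    cdf.to_csv(outdir / "concentration_profiles.csv")
    sdf.to_csv(outdir / "spectral_profiles.csv")
    prov = _provenance(
        config,
        {
            "baseline": {
                "ncomp_method": method,
                "k": k,
                "residual_sse": res.residual_sse,
                "n_iter": res.n_iter,
                "converged": res.converged,
            }
        },
    )
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, default=str)
    return outdir
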