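"""Component-number sweep: pool every MCR-ALS run into the CList dataset.

The factorization is repeated for every component number k = 1 … kmax
(default kmax = number of samples, the largest k the PCA-score
initialization supports) and all resulting concentration/spectrum pairs are
pooled.  Before zero-component removal the pool holds exactly
kmax·(kmax+1)/2 records.  Reliability analysis rests on the observation
that a genuine component re-emerges in most runs while spurious ones appear
only sporadically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mcr import MCRALS, ComponentRecord, drop_zero_components
from .preprocess import BinnedMatrix

__all__ = ["CList", "ComponentRecord", "run_sweep"]


@dataclass
class CList:
    """Pooled concentration (and paired spectral) profiles from a sweep."""

    records: list[ComponentRecord]
    n_samples: int
    n_bins: int
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def concentration_matrix(self) -> np.ndarray:
        """records × samples matrix (the clustering input)."""
        return np.vstack([r.concentration for r in self.records])

    def spectrum_matrix(self) -> np.ndarray:
        return np.vstack([r.spectrum for r in self.records])

    def subset(self, ids: list[str]) -> "CList":
        want = set(ids)
        recs = [r for r in self.records if r.id in want]
        return CList(recs, self.n_samples, self.n_bins, dict(self.provenance))

    def by_id(self) -> dict[str, ComponentRecord]:
        return {r.id: r for r in self.records}

    def to_csv(self, conc_path, spec_path=None, provenance_path=None) -> None:
        pd.DataFrame(
            self.concentration_matrix(),
            index=pd.Index(self.ids, name="record_id"),
            columns=[f"s{i}" for i in range(self.n_samples)],
        ).to_csv(conc_path)
        if spec_path is not None:
            pd.DataFrame(
                self.spectrum_matrix(),
                index=pd.Index(self.ids, name="record_id"),
                columns=[f"b{i}" for i in range(self.n_bins)],
            ).to_csv(spec_path)
        if provenance_path is not None:
            with open(provenance_path, "w") as fh:
                json.dump(self.provenance, fh, indent=2, default=str)

    @classmethod
    def read_csv(cls, conc_path, spec_path=None) -> "CList":
        cdf = pd.read_csv(conc_path, index_col=0)
        sdf = pd.read_csv(spec_path, index_col=0) if spec_path else None
        recs = []
        for i, rid in enumerate(cdf.index):
            k, idx = rid.lstrip("k").split("_c")
            spec = sdf.iloc[i].to_numpy() if sdf is not None else np.zeros(0)
            recs.append(ComponentRecord(int(k), int(idx), cdf.iloc[i].to_numpy(), spec))
        n_bins = sdf.shape[1] if sdf is not None else 0
        return cls(recs, cdf.shape[1], n_bins)


def run_sweep(
    D,
    kmax: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    drop_zeros: bool = True,
    zero_tol: float | None = None,
) -> CList:
    """Run MCR-ALS for every k in 1..kmax and pool the components.

    Runs are independent (no warm starts) and the whole procedure is
    deterministic, so concurrent execution cannot change the output; this
    implementation runs them sequentially in ascending k.
    """
    X = D.values if isinstance(D, BinnedMatrix) else np.asarray(D, dtype=float)
    n, p = X.shape
    if kmax is None:
        kmax = n
    if not 1 <= kmax <= n:
        raise ValueError(f"kmax must be in [1, n_samples={n}], got {kmax}")
    records: list[ComponentRecord] = []
    for k in range(1, kmax + 1):
        try:
            res = MCRALS(X, k).fit(tol=tol, max_iter=max_iter)
        except Exception as exc:  # annotate with the offending k
            raise RuntimeError(f"MCR-ALS failed at k={k}: {exc}") from exc
        if drop_zeros:
            records.extend(drop_zero_components(res, zero_tol))
        else:
            records.extend(res.components())
    return CList(
        records=records,
        n_samples=n,
        n_bins=p,
        provenance={
            "kmax": kmax,
            "tol": tol,
            "max_iter": max_iter,
            "drop_zeros": drop_zeros,
            "raw_count": kmax * (kmax + 1) // 2,
        },
    )
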