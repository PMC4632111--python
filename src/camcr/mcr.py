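"""Non-negativity-constrained MCR-ALS factorization.

Fits the bilinear mixture model ``D = C Sᵗ + E`` — concentration profiles
``C`` (samples × k) and spectral profiles ``S`` (bins × k), both constrained
non-negative — by alternating exact non-negative least squares.  The
concentration matrix is initialized from PCA scores of the column-centered
data and the spectral matrix from all ones; the first half-step solves S
from the (possibly sign-indefinite) score matrix, after which every iterate
is non-negative.  Because each half-step solves its subproblem exactly, the
residual sum of squares is non-increasing across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._nnls import nnls_multi
from .preprocess import BinnedMatrix

__all__ = [
    "MCRALS",
    "MCRALSResults",
    "ComponentRecord",
    "pca_scores_init",
    "als_fit",
    "drop_zero_components",
]


@dataclass
class ComponentRecord:
    """One component of one MCR-ALS run (a concentration/spectrum pair)."""

    run_k: int
    index_in_run: int
    concentration: np.ndarray
    spectrum: np.ndarray

    @property
    def id(self) -> str:
        return f"k{self.run_k}_c{self.index_in_run}"


def _as_array(D) -> np.ndarray:
    if isinstance(D, BinnedMatrix):
        return D.values
    return np.asarray(D, dtype=float)


def pca_scores_init(D, k: int) -> np.ndarray:
    """First ``k`` principal-component scores of the column-centered data.

    No variance scaling (covariance PCA).  Column signs are fixed so each
    score column's largest-magnitude entry is positive, making the
    initialization — and hence the whole sweep — deterministic.
    """
    X = _as_array(D)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, n_samples={n}], got {k}")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :k] * s[:k]
    if scores.shape[1] < k:  # more components requested than SVD returns
        scores = np.hstack([scores, np.zeros((n, k - scores.shape[1]))])
    flip = np.sign(scores[np.abs(scores).argmax(axis=0), np.arange(scores.shape[1])])
    flip[flip == 0] = 1.0
    return scores * flip


@dataclass
class MCRALSResults:
    """Fitted concentration and spectral profiles of one MCR-ALS run."""

    model: "MCRALS | None"
    C: np.ndarray  # samples x k, >= 0
    S: np.ndarray  # bins x k, >= 0
    residual_sse: float
    n_iter: int
    converged: bool
    k_requested: int
    history: np.ndarray | None = None  # residual SSE per iteration
    data_max: float = 1.0  # max entry of D, the reference scale for zero tests

    @property
    def fitted(self) -> np.ndarray:
        return self.C @ self.S.T

    def components(self, zero_tol: float | None = None) -> list[ComponentRecord]:
        recs = [
            ComponentRecord(self.k_requested, j + 1, self.C[:, j].copy(), self.S[:, j].copy())
            for j in range(self.C.shape[1])
        ]
        if zero_tol is not None:
            recs = drop_zero_components(self, zero_tol)
        return recs

    def summary(self) -> str:
        lines = [
            "MCR-ALS results",
            "=" * 40,
            f"components requested : {self.k_requested}",
            f"samples x bins       : {self.C.shape[0]} x {self.S.shape[0]}",
            f"iterations           : {self.n_iter}",
            f"converged            : {self.converged}",
            f"residual SSE         : {self.residual_sse:.6g}",
        ]
        contrib = (self.C**2).sum(axis=0) * (self.S**2).sum(axis=0)
        order = np.argsort(contrib)[::-1]
        lines.append("component  max(C)      max(S)")
        for j in order:
            lines.append(
                f"  {j + 1:>4d}     {self.C[:, j].max():<10.4g}  {self.S[:, j].max():<10.4g}"
            )
        return "\n".join(lines)

    def profiles_frame(self, bin_centers=None, sample_ids=None) -> tuple[pd.DataFrame, pd.DataFrame]:
        cols = [f"c{j + 1}" for j in range(self.C.shape[1])]
        cdf = pd.DataFrame(self.C, columns=cols, index=sample_ids)
        sdf = pd.DataFrame(self.S, columns=cols, index=bin_centers)
        return cdf, sdf


class MCRALS:
    """MCR-ALS model for a non-negative data matrix at a fixed component number.

    Parameters
    ----------
    data : BinnedMatrix or array-like
        Non-negative samples × bins matrix.
    k : int
        Number of components to resolve.
    """

    def __init__(self, data, k: int):
        self.data = data
        X = _as_array(data)
        if X.ndim != 2:
            raise ValueError("data must be a 2-D matrix")
        if not np.all(np.isfinite(X)):
            raise ValueError("data contains non-finite values")
        if np.any(X < 0):
            raise ValueError("MCR-ALS requires non-negative data")
        if k < 1:
            raise ValueError("k must be >= 1")
        self._X = X
        self.k = int(k)

    def fit(
        self,
        tol: float = 1e-8,
        max_iter: int = 200,
        C_init: np.ndarray | None = None,
    ) -> MCRALSResults:
        X = self._X
        if C_init is None:
            C_init = pca_scores_init(X, self.k)
        res = als_fit(X, C_init, tol=tol, max_iter=max_iter)
        res.model = self
        return res


def als_fit(
    D,
    C_init: np.ndarray,
    S_init: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> MCRALSResults:
    """Alternating NNLS: solve S given C (per bin), then C given S (per sample).

    Stops when the relative change in residual SSE falls below ``tol`` or
    after ``max_iter`` full alternations.  ``S_init`` exists only to fix the
    convention that S is solved first (its value is immaterial after the
    first half-step); per the workflow emulated here it defaults to ones.
    """
    X = _as_array(D)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(C_init)):
        raise ValueError("non-finite input")
    n, p = X.shape
    k = C_init.shape[1]
    if k < 1:
        raise ValueError("k must be >= 1")
    if C_init.shape[0] != n:
        raise ValueError("C_init row count must match samples")

    C = np.asarray(C_init, dtype=float)
    sse_prev = np.inf
    history = []
    converged = False
    n_iter = 0
    S = np.ones((p, k)) if S_init is None else np.asarray(S_init, dtype=float)
    for it in range(1, max_iter + 1):
        # S-step: for each bin, min ||X[:, j] - C s_j||, s_j >= 0
        S = nnls_multi(C, X).T  # (k, p).T -> p x k
        # rebalance the scale indeterminacy: unit-max S columns.  The C-step
        # re-solves C from scratch, so this leaves the iteration's products
        # unchanged in exact arithmetic and only protects conditioning
        # (otherwise paired columns drift to eps / 1/eps scales).
        smax = S.max(axis=0)
        nz = smax > 0
        S[:, nz] /= smax[nz]
        # C-step: for each sample, min ||X[i, :] - S c_i||, c_i >= 0
        C = nnls_multi(S, X.T).T  # (k, n).T -> n x k
        sse = float(((X - C @ S.T) ** 2).sum())
        history.append(sse)
        n_iter = it
        denom = max(sse_prev, np.finfo(float).tiny)
        if np.isfinite(sse_prev) and (sse_prev - sse) / denom < tol:
            converged = True
            break
        sse_prev = sse
    return MCRALSResults(
        model=None,
        C=C,
        S=S,
        residual_sse=history[-1],
        n_iter=n_iter,
        converged=converged,
        k_requested=k,
        history=np.asarray(history),
        data_max=float(X.max(initial=0.0)),
    )


def drop_zero_components(result: MCRALSResults, zero_tol: float | None = None) -> list[ComponentRecord]:
    """Remove components whose concentration or spectral column is all ~zero.

    Survivors keep their original run size and within-run index, so a
    record's identity (``k<run>_c<index>``) is stable under removal.
    """
    if zero_tol is None:
        zero_tol = 1e-12 * max(result.data_max, 1.0)
    recs = []
    for j in range(result.C.shape[1]):
        if np.abs(result.C[:, j]).max() <= zero_tol:
            continue
        if np.abs(result.S[:, j]).max() <= zero_tol:
            continue
        recs.append(
            ComponentRecord(
                result.k_requested, j + 1, result.C[:, j].copy(), result.S[:, j].copy()
            )
        )
    return recs
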