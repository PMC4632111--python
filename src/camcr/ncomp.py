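"""Conventional number-of-components estimators on a shared eigenvalue spectrum.

Eight classical strategies for choosing the component count of a PCA-style
decomposition: Kaiser criterion, scree export (visual), Horn's parallel
analysis, the Cattell–Nelson–Gorsuch slope test, its multiple-regression
extension, generalized cross-validation, an approximate leave-one-out
(smoothing) criterion, and the cumulative-contribution rule.  They often
disagree on real data — the motivation for reliability-based component
selection — and are provided both as a baseline and for the conventional
single-fit workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import BinnedMatrix

__all__ = [
    "EigSpectrum",
    "eig_spectrum",
    "kaiser",
    "parallel_analysis",
    "cng",
    "mreg",
    "cv_gcv",
    "cv_smooth",
    "cum_contribution",
    "scree_export",
    "estimate_all",
]


def _as_array(D) -> np.ndarray:
    if isinstance(D, BinnedMatrix):
        return D.values
    return np.asarray(D, dtype=float)


@dataclass
class EigSpectrum:
    """Descending eigenvalues of the (co)variance matrix of centered data."""

    eigenvalues: np.ndarray
    standardized: bool
    n_samples: int
    n_vars: int

    def __len__(self) -> int:
        return len(self.eigenvalues)

    @property
    def shares(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        if tot <= 0:
            raise ValueError("spectrum has zero total variance")
        return self.eigenvalues / tot


def eig_spectrum(D, standardize: bool = False) -> EigSpectrum:
    """Eigenvalues of the covariance (or correlation) matrix of centered D.

    Computed as squared singular values of the centered (optionally
    unit-variance scaled) data divided by n − 1; length min(n − 1, p), the
    number of components a PCA of the data can produce.
    """
    X = _as_array(D)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    if standardize:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    s = np.linalg.svd(Xc, compute_uv=False)
    eig = (s**2) / (n - 1)
    eig = eig[: min(n - 1, p)]
    return EigSpectrum(
        eigenvalues=np.sort(eig)[::-1], standardized=standardize,
        n_samples=n, n_vars=p,
    )


def kaiser(spec: EigSpectrum) -> int:
    """Count of eigenvalues exceeding 1 (meaningful for correlation PCA)."""
    if not spec.standardized:
        import warnings

        warnings.warn(
            "Kaiser criterion assumes a correlation-matrix (standardized) spectrum",
            stacklevel=2,
        )
    return int((spec.eigenvalues > 1.0).sum())


def parallel_analysis(
    D, n_rep: int = 100, quantile: float | None = None, seed: int = 0
) -> int:
    """Horn's parallel analysis against standard-normal data of the same shape.

    The observed correlation-matrix spectrum is compared position by
    position with the mean (or given quantile) of n_rep random spectra; the
    count of leading positions where the observed eigenvalue exceeds the
    reference is returned.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    X = _as_array(D)
    n, p = X.shape
    obs = eig_spectrum(X, standardize=True).eigenvalues
    rng = np.random.default_rng(seed)
    rand = np.empty((n_rep, len(obs)))
    for i in range(n_rep):
        R = rng.standard_normal((n, p))
        rand[i] = eig_spectrum(R, standardize=True).eigenvalues
    ref = rand.mean(axis=0) if quantile is None else np.quantile(rand, quantile, axis=0)
    above = obs > ref
    k = 0
    for flag in above:
        if not flag:
            break
        k += 1
    return k


def _slope(y: np.ndarray) -> float:
    x = np.arange(len(y), dtype=float)
    return float(np.polyfit(x, y, 1)[0])


def cng(spec: EigSpectrum) -> int:
    """Cattell–Nelson–Gorsuch test: scan 3+3 eigenvalue windows.

    At each position the slope of three leading eigenvalues is compared to
    the slope of the next three; the retained count is the last eigenvalue
    of the leading window at the position of maximal slope gain (so the
    estimate is never below 3).  Ties break at the first position.
    """
    eig = spec.eigenvalues
    if len(eig) < 6:
        raise ValueError("CNG needs at least 6 eigenvalues")
    diffs = np.array(
        [
            _slope(eig[i + 3 : i + 6]) - _slope(eig[i : i + 3])
            for i in range(len(eig) - 5)
        ]
    )
    # first position within numerical noise of the maximum (tie-break rule)
    best = diffs.max()
    atol = 1e-9 * (1.0 + abs(best))
    return int(np.flatnonzero(diffs >= best - atol)[0]) + 3


def mreg(spec: EigSpectrum) -> int:
    """Two-regression-line scan: split maximizing the normalized slope gap.

    For every split k the spectrum is fitted by one line over eigenvalues
    1..k and another over k+1..end; the score is the slope difference
    divided by the pooled residual standard error.  Returns the argmax split
    (first position on ties; on break-free spectra this degenerates to a
    boundary candidate).
    """
    eig = spec.eigenvalues
    L = len(eig)
    if L < 6:
        raise ValueError("mreg needs at least 6 eigenvalues")
    x = np.arange(L, dtype=float)
    best_k, best_score = 2, -np.inf
    for k in range(2, L - 1):
        b1, a1 = np.polyfit(x[:k], eig[:k], 1)
        b2, a2 = np.polyfit(x[k:], eig[k:], 1)
        r1 = eig[:k] - (a1 + b1 * x[:k])
        r2 = eig[k:] - (a2 + b2 * x[k:])
        dof = max(L - 4, 1)
        s = np.sqrt((np.sum(r1**2) + np.sum(r2**2)) / dof)
        score = (b2 - b1) / (s + 1e-12)
        if score > best_score + 1e-12:
            best_score, best_k = score, k
    return best_k


def _centered_svd(X: np.ndarray):
    Xc = X - X.mean(axis=0, keepdims=True)
    return np.linalg.svd(Xc, full_matrices=False), Xc


def cv_gcv(D, kmax: int | None = None) -> int:
    """Generalized cross-validation for the truncated-SVD reconstruction.

    GCV(k) = RSS(k) / (np · (1 − df(k)/np)²) with df(k) = p + k(n + p − k)
    (column means plus the free parameters of a rank-k SVD); returns the
    argmin over k = 0..kmax.
    """
    X = _as_array(D)
    n, p = X.shape
    hard_max = min(n, p) - 1
    if kmax is None:
        kmax = hard_max
    if not 1 <= kmax <= hard_max:
        raise ValueError(f"kmax must be in [1, {hard_max}]")
    (U, s, Vt), _ = _centered_svd(X)
    total = float((s**2).sum())
    rss = total - np.concatenate([[0.0], np.cumsum(s**2)])  # rss[k]
    npnt = n * p
    best_k, best = 0, np.inf
    for k in range(0, kmax + 1):
        df = p + k * (n + p - k)
        if df >= npnt:
            break
        g = rss[k] / (npnt * (1 - df / npnt) ** 2)
        if g < best - 1e-15:
            best, best_k = g, k
    return best_k


def cv_smooth(D, kmax: int | None = None) -> int:
    """Approximate leave-one-out (PRESS) via per-cell leverage smoothing.

    Treats the rank-k PCA reconstruction as a linear smoother with cell
    leverage h_ij = 1/n + Σ_l≤k (u_il² + v_jl²) and scores each k by
    Σ (e_ij / (1 − h_ij))²; returns the argmin.
    """
    X = _as_array(D)
    n, p = X.shape
    hard_max = min(n, p) - 1
    if kmax is None:
        kmax = hard_max
    if not 1 <= kmax <= hard_max:
        raise ValueError(f"kmax must be in [1, {hard_max}]")
    (U, s, Vt), Xc = _centered_svd(X)
    best_k, best = 0, np.inf
    E = Xc.copy()
    H = np.full((n, p), 1.0 / n)
    for k in range(0, kmax + 1):
        if k > 0:
            comp = np.outer(U[:, k - 1] * s[k - 1], Vt[k - 1])
            E = E - comp
            H = H + U[:, k - 1, None] ** 2 + Vt[None, k - 1, :] ** 2
        Hc = np.minimum(H, 0.99)
        press = float(((E / (1.0 - Hc)) ** 2).sum())
        if press < best - 1e-15:
            best, best_k = press, k
    return best_k


def cum_contribution(spec: EigSpectrum, level: float = 0.90) -> int:
    """Smallest k whose cumulative eigenvalue share exceeds ``level``."""
    shares = np.cumsum(spec.shares)
    if level >= 1.0:
        return len(shares)
    return int(np.searchsorted(shares, level, side="right")) + 1


def scree_export(spec: EigSpectrum) -> pd.DataFrame:
    """Eigenvalue table for external scree plotting (visual method)."""
    return pd.DataFrame(
        {
            "component": np.arange(1, len(spec) + 1),
            "eigenvalue": spec.eigenvalues,
        }
    )


def estimate_all(D, n_rep: int = 100, seed: int = 0, level: float = 0.90) -> pd.DataFrame:
    """Run every automated estimator on one matrix; one row per method."""
    spec_std = eig_spectrum(D, standardize=True)
    spec_cov = eig_spectrum(D, standardize=False)
    rows = [("kaiser", kaiser(spec_std))]
    rows.append(("parallel_analysis", parallel_analysis(D, n_rep=n_rep, seed=seed)))
    for name, fn, spec in (
        ("cng", cng, spec_cov),
        ("mreg", mreg, spec_cov),
    ):
        try:
            rows.append((name, fn(spec)))
        except ValueError as exc:
            rows.append((name, f"n/a ({exc})"))
    rows.append(("cv_gcv", cv_gcv(D)))
    rows.append(("cv_smooth", cv_smooth(D)))
    rows.append(("cum_contribution", cum_contribution(spec_cov, level=level)))
    rows.append(("scree", "visual (see scree_export)"))
    return pd.DataFrame(rows, columns=["method", "n_components"])
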