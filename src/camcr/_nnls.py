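"""Multi right-hand-side non-negative least squares.

Exact active-set solver for ``min_{X >= 0} ||A X - B||_F`` with many columns
in ``B`` sharing the design matrix ``A`` (fast combinatorial NNLS: columns
with the same passive set share one normal-equation solve).  Exactness of
each subproblem solution is what guarantees the monotone-residual property
of the alternating least squares loop built on top of it.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

__all__ = ["nnls_multi"]


def _cssls(AtA: np.ndarray, AtB: np.ndarray, passive: np.ndarray | None) -> np.ndarray:
    """Solve the normal equations restricted to each column's passive set.

    Columns are grouped by identical passive sets so each distinct set costs
    one (small) linear solve.  Singular subsets fall back to lstsq.
    """
    k, n = AtB.shape
    X = np.zeros((k, n))
    if passive is None:
        try:
            return np.linalg.solve(AtA, AtB)
        except np.linalg.LinAlgError:
            return np.linalg.lstsq(AtA, AtB, rcond=None)[0]
    # group columns by passive-set pattern
    codes = np.packbits(passive, axis=0).T  # n x ceil(k/8)
    order = np.lexsort(codes.T[::-1])
    sorted_codes = codes[order]
    boundaries = np.ones(n, dtype=bool)
    if n > 1:
        boundaries[1:] = np.any(sorted_codes[1:] != sorted_codes[:-1], axis=1)
    starts = np.flatnonzero(boundaries)
    for gi, s in enumerate(starts):
        e = starts[gi + 1] if gi + 1 < len(starts) else n
        cols = order[s:e]
        pset = passive[:, cols[0]]
        if not pset.any():
            continue
        sub = AtA[np.ix_(pset, pset)]
        rhs = AtB[np.ix_(pset, cols)]
        try:
            sol = np.linalg.solve(sub, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(sub, rhs, rcond=None)[0]
        block = np.zeros((k, len(cols)))
        block[pset, :] = sol
        X[:, cols] = block
    return X


def nnls_multi(A: np.ndarray, B: np.ndarray, tol: float | None = None) -> np.ndarray:
    """Return ``X >= 0`` minimising ``||A X - B||_F`` column by column.

    Parameters
    ----------
    A : (m, k) design matrix (need not be non-negative).
    B : (m, n) right-hand sides.
    tol : optimality tolerance on the dual (gradient) entries; default scales
        with the data.

    Columns that fail to converge within the iteration budget (rare cycling
    of the combinatorial active-set scheme) are re-solved one at a time with
    scipy's Lawson–Hanson implementation.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if B.ndim == 1:
        B = B[:, None]
    m, k = A.shape
    n = B.shape[1]
    AtA = A.T @ A
    AtB = A.T @ B
    if tol is None:
        tol = 10 * np.finfo(float).eps * max(np.abs(AtA).max(), 1.0) * k

    X = _cssls(AtA, AtB, None)
    passive = X > 0
    X[~passive] = 0.0
    todo = np.flatnonzero(~passive.all(axis=0))
    D = X.copy()

    max_outer = 5 * k + 20
    iters = 0
    outer = 0
    failed: list[int] = []
    while todo.size:
        outer += 1
        if outer > max_outer:
            # singular / degenerate Gram matrices can make the combinatorial
            # scheme cycle; hand the stragglers to Lawson–Hanson
            failed.extend(todo.tolist())
            X[:, todo] = 0.0
            break
        X[:, todo] = _cssls(AtA, AtB[:, todo], passive[:, todo])
        infeas = todo[np.any(X[:, todo] < -tol, axis=0)]
        inner = 0
        while infeas.size:
            inner += 1
            iters += 1
            if iters > max_outer and inner > 2 * k + 10:
                failed.extend(infeas.tolist())
                X[:, infeas] = 0.0
                passive[:, infeas] = False
                todo = np.setdiff1d(todo, infeas)
                infeas = np.array([], dtype=int)
                break
            Xh = X[:, infeas]
            Dh = D[:, infeas]
            mask = passive[:, infeas] & (Xh < -tol)
            alpha = np.full_like(Xh, np.inf)
            denom = Dh - Xh
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(mask & (denom > 0), Dh / denom, np.inf)
            alpha = ratio
            amin = alpha.min(axis=0)
            amin_idx = alpha.argmin(axis=0)
            stuck = ~np.isfinite(amin)
            if stuck.any():  # no feasible step: hand to Lawson-Hanson later
                bad = infeas[stuck]
                failed.extend(bad.tolist())
                X[:, bad] = 0.0
                passive[:, bad] = False
                todo = np.setdiff1d(todo, bad)
                infeas = infeas[~stuck]
                if not infeas.size:
                    break
                Xh = X[:, infeas]
                Dh = D[:, infeas]
                amin = amin[~stuck]
                amin_idx = amin_idx[~stuck]
            Dh = Dh - amin[None, :] * (Dh - Xh)
            Dh[amin_idx, np.arange(len(infeas))] = 0.0
            D[:, infeas] = Dh
            passive[amin_idx, infeas] = False
            X[:, infeas] = _cssls(AtA, AtB[:, infeas], passive[:, infeas])
            infeas = infeas[np.any(X[:, infeas] < -tol, axis=0)]
        if not todo.size:
            break
        W = AtB[:, todo] - AtA @ X[:, todo]
        # a column is optimal when every zero (non-passive) coordinate has
        # non-positive gradient
        opt = np.all(np.where(passive[:, todo], -np.inf, W) <= tol, axis=0)
        done = todo[opt]
        D[:, done] = X[:, done]
        todo = todo[~opt]
        if todo.size:
            Wm = np.where(passive[:, todo], -np.inf, W[:, ~opt])
            add = Wm.argmax(axis=0)
            passive[add, todo] = True
            D[:, todo] = X[:, todo]
    if failed:
        for j in failed:
            X[:, j], _ = _scipy_nnls(A, B[:, j])
    np.clip(X, 0.0, None, out=X)
    return X
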