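"""MCR-ALS core: initialization, alternating NNLS, zero-component removal."""

import numpy as np
import pytest
from scipy.optimize import nnls as scipy_nnls

from camcr._nnls import nnls_multi
from camcr.mcr import MCRALS, als_fit, drop_zero_components, pca_scores_init
from camcr.synth import (
    CompoundTemplate,
    ConcentrationDesign,
    default_ppm_grid,
    simulate_dataset,
)


def _matched_correlations(true_C, est_C):
    """Best |r| match per true column (profiles identifiable up to perm/scale)."""
    out = []
    for j in range(true_C.shape[1]):
        rs = [
            abs(np.corrcoef(true_C[:, j], est_C[:, c])[0, 1])
            for c in range(est_C.shape[1])
            if est_C[:, c].std() > 0
        ]
        out.append(max(rs))
    return np.array(out)


class TestNNLSMulti:
    def test_matches_scipy_oracle(self, rng):
        for _ in range(25):
            m, k, n = rng.integers(3, 15), rng.integers(1, 10), rng.integers(1, 12)
            A = rng.normal(size=(m, k))
            B = rng.normal(size=(m, n))
            X = nnls_multi(A, B)
            assert np.all(X >= 0)
            for j in range(n):
                _, r0 = scipy_nnls(A, B[:, j])
                r1 = np.linalg.norm(A @ X[:, j] - B[:, j])
                assert r1 <= r0 + 1e-8 * (1 + r0)

    def test_underdetermined_does_not_cycle(self, rng):
        A = rng.normal(size=(4, 9))
        B = rng.normal(size=(4, 6))
        X = nnls_multi(A, B)
        for j in range(6):
            _, r0 = scipy_nnls(A, B[:, j])
            assert np.linalg.norm(A @ X[:, j] - B[:, j]) <= r0 + 1e-7 * (1 + r0)


class TestPCAScoresInit:
    def test_rank_one_scores_proportional_to_centered_factor(self, rng):
        a = rng.uniform(1, 2, 8)
        b = rng.uniform(1, 2, 12)
        scores = pca_scores_init(np.outer(a, b), 1)
        ac = a - a.mean()
        r = np.corrcoef(scores[:, 0], ac)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_full_rank_reconstruction(self, rng):
        # SVD oracle: scores+loadings reconstruct the centered data
        X = rng.uniform(0, 1, (6, 10))
        Xc = X - X.mean(axis=0)
        scores = pca_scores_init(X, 6)
        # project back: Xc = scores @ Vt where Vt = pinv(scores) @ Xc
        recon = scores @ (np.linalg.pinv(scores) @ Xc)
        np.testing.assert_allclose(recon, Xc, atol=1e-8)

    def test_k_out_of_range(self, rng):
        X = rng.uniform(0, 1, (5, 8))
        with pytest.raises(ValueError):
            pca_scores_init(X, 6)
        with pytest.raises(ValueError):
            pca_scores_init(X, 0)

    def test_sign_convention_deterministic(self, rng):
        X = rng.uniform(0, 1, (7, 9))
        s1 = pca_scores_init(X, 3)
        s2 = pca_scores_init(X.copy(), 3)
        np.testing.assert_array_equal(s1, s2)
        for j in range(3):
            assert s1[np.abs(s1[:, j]).argmax(), j] > 0


class TestALSFit:
    def _exact_dataset(self, seed=0, n=12, k=3, bins=120):
        rng = np.random.default_rng(seed)
        grid = default_ppm_grid(bins)
        centers = np.linspace(1, 9, k)
        lib = [CompoundTemplate(f"c{i}", [(c, 0.05, 1.0)]) for i, c in enumerate(centers)]
        C = rng.uniform(0, 1, (n, k))
        C *= rng.random(C.shape) < 0.7
        C[C.sum(axis=1) == 0, 0] = 0.5  # avoid empty samples
        design = ConcentrationDesign(C, [t.name for t in lib])
        return simulate_dataset(lib, design, grid, noise_sd=0.0, seed=seed)

    def test_exact_recovery_up_to_permutation_scale(self):
        ds = self._exact_dataset(seed=3)
        res = MCRALS(ds.data, 3).fit(tol=1e-12, max_iter=500)
        X = ds.data.values
        assert res.residual_sse / (X**2).sum() < 1e-6
        corr = _matched_correlations(ds.true_concentrations.matrix, res.C)
        assert np.all(corr > 0.999)
        assert np.all(res.C >= 0) and np.all(res.S >= 0)

    def test_rank_one_residual_zero(self, rng):
        D = np.outer(rng.uniform(0.5, 1, 6), rng.uniform(0.5, 1, 9))
        res = MCRALS(D, 1).fit(tol=1e-14, max_iter=100)
        assert res.residual_sse / (D**2).sum() < 1e-12

    def test_single_alternation(self, rng):
        D = rng.uniform(0, 1, (6, 9))
        res = als_fit(D, pca_scores_init(D, 2), tol=0.0, max_iter=1)
        assert res.n_iter == 1
        # residual after the C-step cannot exceed the residual after only
        # the S-step (each exact NNLS half-step is non-increasing)
        S = nnls_multi(pca_scores_init(D, 2), D).T
        C_half = pca_scores_init(D, 2)
        sse_half = ((D - np.clip(C_half, 0, None) @ S.T) ** 2).sum()
        assert res.residual_sse <= sse_half + 1e-10

    def test_monotone_residual(self, rng):
        for _ in range(10):
            D = rng.uniform(0, 1, (8, 15))
            res = als_fit(D, pca_scores_init(D, 3), tol=0.0, max_iter=25)
            diffs = np.diff(res.history)
            assert np.all(diffs <= 1e-10 * (1 + res.history[:-1]))

    def test_rejects_bad_input(self, rng):
        D = rng.uniform(0, 1, (5, 7))
        with pytest.raises(ValueError):
            MCRALS(np.array([[1.0, np.nan], [0.0, 1.0]]), 1)
        with pytest.raises(ValueError):
            MCRALS(-D, 2)
        with pytest.raises(ValueError):
            MCRALS(D, 0)


class TestDropZeroComponents:
    def _result(self, C, S):
        from camcr.mcr import MCRALSResults

        return MCRALSResults(
            model=None, C=C, S=S, residual_sse=0.0, n_iter=1, converged=True,
            k_requested=C.shape[1],
        )

    def test_zero_concentration_column_dropped(self):
        C = np.array([[1.0, 0.0], [2.0, 0.0]])
        S = np.ones((4, 2))
        recs = drop_zero_components(self._result(C, S))
        assert [r.index_in_run for r in recs] == [1]
        assert recs[0].run_k == 2

    def test_all_nonzero_preserved(self, rng):
        C = rng.uniform(0.5, 1, (3, 4))
        S = rng.uniform(0.5, 1, (6, 4))
        assert len(drop_zero_components(self._result(C, S))) == 4

    def test_overfactored_rank3_data(self):
        ds = TestALSFit()._exact_dataset(seed=5, k=3)
        res = MCRALS(ds.data, 6).fit(tol=1e-12, max_iter=300)
        recs = drop_zero_components(res)
        assert len(recs) <= 6
        # survivors still reconstruct the data
        recon = sum(np.outer(r.concentration, r.spectrum) for r in recs)
        X = ds.data.values
        assert ((X - recon) ** 2).sum() / (X**2).sum() < 1e-6
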