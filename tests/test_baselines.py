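import numpy as np
import pytest

import usdeblur as u
from usdeblur import baselines
from usdeblur.core import PSFKernel
from helpers import (
    circulant_matrix,
    coordinate_descent_l1,
    l1_objective,
    solve_tv_by_cd,
    tv_objective,
)


@pytest.fixture
def small_instance(rng):
    """Length-16 circulant problem with a short bell kernel and sparse truth."""
    psf = PSFKernel(np.array([0.3, 1.0, 0.3]), peak_index=1, normalized=True)
    M = circulant_matrix(psf, 16)
    x = np.zeros(16)
    x[[3, 11]] = [1.0, 0.7]
    y = M @ x
    return psf, M, x, y


class TestWiener:
    def test_near_zero_lambda_inverts_exactly(self, small_instance):
        psf, M, x, y = small_instance
        out = u.wiener_deconvolve(y, psf, lam=1e-12, kernel_norm="none")
        np.testing.assert_allclose(out, x, rtol=1e-6, atol=1e-8)

    def test_large_lambda_matched_filter_limit(self, small_instance):
        psf, M, x, y = small_instance
        lam = 1e8
        out = u.wiener_deconvolve(y, psf, lam=lam, kernel_norm="none")
        np.testing.assert_allclose(out, (M.T @ y) / lam, rtol=1e-6, atol=1e-15)

    def test_matches_dense_normal_equations(self, small_instance):
        psf, M, x, y = small_instance
        lam = 0.08
        oracle = np.linalg.solve(M.T @ M + lam * np.eye(16), M.T @ y)
        out = u.wiener_deconvolve(y, psf, lam=lam, kernel_norm="none")
        np.testing.assert_allclose(out, oracle, atol=1e-8)

    def test_area_mode_is_lambda_rescaling(self, small_instance, rng):
        psf, M, x, y = small_instance
        area = float(np.sum(np.abs(psf.samples)))
        a = u.wiener_deconvolve(y, psf, lam=0.05, kernel_norm="area")
        b = u.wiener_deconvolve(y, psf, lam=0.05 * area**2, kernel_norm="none")
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_linearity(self, small_instance):
        psf, M, x, y = small_instance
        np.testing.assert_allclose(
            u.wiener_deconvolve(2.5 * y, psf), 2.5 * u.wiener_deconvolve(y, psf), atol=1e-10
        )

    def test_zero_psf_rejected(self):
        with pytest.raises(ValueError):
            u.wiener_deconvolve(np.ones(16), PSFKernel(np.zeros(3)))


class TestL1:
    def test_objective_matches_coordinate_descent_oracle(self, small_instance):
        psf, M, x, y = small_instance
        lam = 0.1
        ours = u.l1_deconvolve(y, psf, lam=lam, max_iter=20000, tol=1e-14, kernel_norm="none")
        oracle = coordinate_descent_l1(M, y, lam)
        assert abs(l1_objective(M, y, lam, ours) - l1_objective(M, y, lam, oracle)) <= 1e-6

    def test_large_lambda_kills_all_coordinates(self, small_instance):
        psf, M, x, y = small_instance
        lam = float(np.abs(M.T @ y).max()) * 1.001
        out = u.l1_deconvolve(y, psf, lam=lam, kernel_norm="none")
        assert not np.any(out)

    def test_sparser_than_wiener_on_sparse_truth(self, small_instance):
        psf, M, x, y = small_instance
        xl = u.l1_deconvolve(y, psf, lam=0.1, kernel_norm="none", max_iter=5000, tol=1e-12)
        xw = u.wiener_deconvolve(y, psf, lam=0.1, kernel_norm="none")
        assert np.sum(np.abs(xl) > 1e-6) < np.sum(np.abs(xw) > 1e-6)

    def test_objective_monotonically_non_increasing(self, small_instance):
        psf, M, x, y = small_instance
        _, info = u.l1_deconvolve(y, psf, lam=0.1, return_info=True)
        assert np.all(np.diff(info["objective"]) <= 1e-10)

    def test_nonneg_flag_clamps(self, small_instance):
        psf, M, x, y = small_instance
        out = u.l1_deconvolve(y, psf, lam=0.05, nonneg=True, max_iter=2000)
        assert out.min() >= 0.0


class TestTVProx:
    def test_matches_reparam_oracle(self, rng):
        for lam in (0.05, 0.3, 1.0):
            v = rng.standard_normal(12)
            ours = u.tv1d_prox(v, lam)
            oracle = solve_tv_by_cd(np.eye(12), v, lam)
            assert abs(
                tv_objective(np.eye(12), v, lam, ours) - tv_objective(np.eye(12), v, lam, oracle)
            ) <= 1e-8
            np.testing.assert_allclose(ours, oracle, atol=1e-4)

    def test_large_lambda_returns_mean(self, rng):
        v = rng.standard_normal(10)
        np.testing.assert_allclose(u.tv1d_prox(v, 100.0), np.mean(v), atol=1e-10)

    def test_zero_lambda_identity(self, rng):
        v = rng.standard_normal(10)
        np.testing.assert_array_equal(u.tv1d_prox(v, 0.0), v)


class TestTVDeconvolve:
    def test_objective_matches_convex_oracle(self, small_instance):
        psf, M, x, y = small_instance
        lam = 0.1
        ours = u.tv_deconvolve(y, psf, lam=lam, max_iter=30000, tol=1e-14, kernel_norm="none")
        oracle = solve_tv_by_cd(M, y, lam)
        assert abs(tv_objective(M, y, lam, ours) - tv_objective(M, y, lam, oracle)) <= 1e-5

    def test_near_zero_lambda_inverts(self, small_instance):
        psf, M, x, y = small_instance
        out = u.tv_deconvolve(y, psf, lam=1e-10, max_iter=50000, tol=1e-16, kernel_norm="none")
        np.testing.assert_allclose(out, x, atol=1e-3)

    def test_output_tv_not_larger_than_input(self, small_instance, rng):
        # piecewise-constant truth under mild blur: the prox path cannot roughen
        psf, M, _, _ = small_instance
        x = np.repeat([0.0, 1.0, 0.2], [5, 6, 5])
        y = M @ x + 0.01 * rng.standard_normal(16)
        out = u.tv_deconvolve(y, psf, lam=0.2, kernel_norm="none", max_iter=3000)
        tv = lambda v: np.sum(np.abs(np.diff(v)))
        assert tv(out) <= tv(y) + 1e-9

    def test_objective_monotone(self, small_instance):
        psf, M, x, y = small_instance
        _, info = u.tv_deconvolve(y, psf, lam=0.1, return_info=True)
        assert np.all(np.diff(info["objective"]) <= 1e-10)


class TestOnSimulations:
    def test_all_methods_reduce_raw_nmse_vs_envelope(self):
        """On pulse-blurred sparse lines at SNR >= 14 dB every deconvolver
        should, on average, move the signal closer to the truth than the raw
        envelope is (unnormalized error ratio, 20 replicates)."""
        gains = {m: [] for m in ("greedy", "wiener", "l1", "tv")}
        for r in range(20):
            cfg = u.SimConfig(density=0.05, snr_db=14.0, seed=4000 + r)
            rf, truth, psf = u.simulate_rf_line(cfg)
            env = u.envelope(rf)
            pe = u.normalize_psf_envelope(psf)
            base = u.nmse(env.samples, truth.reflectivity, normalize=False)
            sp = u.greedy_deconvolve(env.samples, pe)
            outs = {
                "greedy": u.spikes_to_signal(sp, 512),
                "wiener": u.wiener_deconvolve(env.samples, pe),
                "l1": u.l1_deconvolve(env.samples, pe),
                "tv": u.tv_deconvolve(env.samples, pe, max_iter=300),
            }
            for m, xh in outs.items():
                gains[m].append(base - u.nmse(xh, truth.reflectivity, normalize=False))
        for m, g in gains.items():
            assert np.mean(g) > 0, f"{m} did not reduce nMSE on average"
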