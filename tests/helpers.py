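"""Shared test utilities and independent oracle solvers.

The oracles here deliberately avoid the package's solution paths: dense
linear algebra for the circulant Wiener solve, and coordinate descent for
the l1 / TV objectives (TV via the difference reparameterisation).
"""

import numpy as np


def place_kernel(env, psf_env, position, amplitude):
    """Add amplitude * kernel with its peak at `position` (edge-truncated)."""
    p = psf_env.samples
    lo = position - psf_env.peak_index
    s0, s1 = max(lo, 0), min(lo + p.size, env.size)
    env[s0:s1] += amplitude * p[s0 - lo : s1 - lo]
    return env


def circulant_matrix(psf, n):
    """Dense matrix of the circulant convolution operator (kernel peak at lag 0)."""
    h = np.zeros(n)
    p = psf.samples
    h[: p.size] = p
    h = np.roll(h, -psf.peak_index)
    spec = np.fft.fft(h)
    cols = [np.fft.ifft(spec * np.fft.fft(np.eye(n)[:, j])).real for j in range(n)]
    return np.stack(cols, axis=1)


def coordinate_descent_l1(A, y, lam, weights=None, n_sweeps=4000, tol=1e-14):
    """Cyclic coordinate descent for 0.5||y - A theta||^2 + sum_j w_j lam |theta_j|."""
    n = A.shape[1]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    theta = np.zeros(n)
    col_sq = np.einsum("ij,ij->j", A, A)
    r = y.copy()
    prev_obj = np.inf
    for _ in range(n_sweeps):
        for j in range(n):
            if col_sq[j] == 0:
                continue
            r += A[:, j] * theta[j]
            b = A[:, j] @ r
            t = lam * w[j]
            theta[j] = np.sign(b) * max(abs(b) - t, 0.0) / col_sq[j]
            r -= A[:, j] * theta[j]
        obj = 0.5 * float(r @ r) + lam * float(np.sum(w * np.abs(theta)))
        if prev_obj - obj < tol:
            break
        prev_obj = obj
    return theta


def l1_objective(A, y, lam, x):
    r = y - A @ x
    return 0.5 * float(r @ r) + lam * float(np.sum(np.abs(x)))


def tv_objective(A, y, lam, x):
    r = y - A @ x
    return 0.5 * float(r @ r) + lam * float(np.sum(np.abs(np.diff(x))))


def tv_reparam_basis(n):
    """x = B theta with theta = (x_0, d_1..d_{n-1}): lower-triangular cumsum basis."""
    return np.tril(np.ones((n, n)))


def solve_tv_by_cd(A, y, lam, n_sweeps=6000):
    """TV problem via l1 coordinate descent on the difference reparameterisation."""
    n = A.shape[1]
    B = tv_reparam_basis(n)
    weights = np.ones(n)
    weights[0] = 0.0  # the level term is unpenalized
    theta = coordinate_descent_l1(A @ B, y, lam, weights=weights, n_sweeps=n_sweeps)
    return B @ theta
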