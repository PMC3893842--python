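"""Noninverse greedy deconvolution of an envelope line.

The sparse reflectivity is recovered without ever inverting the pulse
spectrum, by a matching-pursuit-style loop on the envelope:

    R_0 = envelope
    repeat: n_i = argmax R_i;  a_i = R_i(n_i)
            stop if a_i <= k
            record spike (n_i, a_i)
            R_{i+1}(n) = R_i(n) - a_i * p(n - n_i + peak)    (p: unit-peak
            pulse envelope, truncated at the signal edges; negative residual
            samples optionally clipped to zero)

Because the pulse envelope is nonnegative with unit peak, each iteration
zeroes the current argmax and the residual maximum strictly decreases, so
with k = 0 and clipping on the loop terminates in at most N iterations.  The
number of iterations equals the number of recorded spikes — the sparsity
coefficient of the output.

Argmax ties break to the lowest index; the recorded amplitude is the
residual's value at the pick, which preserves the envelope amplitude scale
in the recovered spike train.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.signal import hilbert

from .core import EnvelopeLine, PSFKernel, SparseSpikes

__all__ = ["GreedyConfig", "normalize_psf_envelope", "greedy_deconvolve", "spikes_to_signal"]


@dataclass
class GreedyConfig:
    """Exit level ``k_threshold`` (k = 0 extracts every possible reflector),
    iteration cap, and negative-residual clipping switch."""

    k_threshold: float = 0.0
    max_iterations: Optional[int] = None  # None -> signal length
    clip_negative: bool = True

    def __post_init__(self) -> None:
        if self.k_threshold < 0:
            raise ValueError("k_threshold must be >= 0")
        if self.max_iterations is not None and self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def normalize_psf_envelope(psf: Union[PSFKernel, np.ndarray]) -> PSFKernel:
    """Envelope form of a pulse, scaled to unit peak.

    An RF-form kernel (one with substantial negative excursions, i.e. a
    carrier-modulated pulse) is demodulated to its envelope via the analytic
    signal.  A baseband kernel with only small negative ripple (such as a
    minimum-phase homomorphic estimate) is clipped instead: the analytic
    envelope of an already-lowpass bell has heavy Hilbert tails that would
    artificially widen it.  Idempotent on a unit-peak nonnegative kernel.
    """
    if isinstance(psf, PSFKernel):
        p, fs = psf.samples, psf.fs
    else:
        p, fs = np.asarray(psf, dtype=float), 20e6
    if p.size < 2:
        raise ValueError("PSF must have at least 2 samples")
    if np.any(p < 0):
        if p.min() < -0.1 * p.max():  # oscillating RF pulse -> demodulate
            p = np.abs(hilbert(p))
        else:  # quasi-envelope kernel -> remove ripple
            p = np.maximum(p, 0.0)
    m = p.max()
    if m <= 0:
        raise ValueError("PSF must have a positive maximum")
    p = p / m
    return PSFKernel(p, fs=fs, peak_index=int(np.argmax(p)), normalized=True)


def greedy_deconvolve(
    env: Union[EnvelopeLine, np.ndarray],
    psf_env: PSFKernel,
    cfg: Optional[GreedyConfig] = None,
) -> SparseSpikes:
    """Run the greedy loop; see the module docstring for the iteration."""
    cfg = cfg or GreedyConfig()
    y = env.samples if isinstance(env, EnvelopeLine) else np.asarray(env, dtype=float)
    if y.ndim != 1:
        raise ValueError("expected a one-dimensional envelope")
    if y.size and y.min() < 0:
        raise ValueError("envelope must be nonnegative")
    p = psf_env.samples
    if not psf_env.normalized or abs(p.max() - 1.0) > 1e-9 or p.min() < 0:
        raise ValueError("psf_env must be a nonnegative unit-peak envelope kernel")

    r = y.astype(float).copy()
    n = r.size
    pk = psf_env.peak_index
    m = p.size
    max_iter = cfg.max_iterations if cfg.max_iterations is not None else n
    positions, amplitudes, history = [], [], []
    clipped = np.zeros(n)
    for _ in range(max_iter):
        ni = int(np.argmax(r))  # ties -> lowest index
        ai = float(r[ni])
        if ai <= cfg.k_threshold:
            break
        positions.append(ni)
        amplitudes.append(ai)
        history.append(ai)
        lo = ni - pk
        s0, s1 = max(lo, 0), min(lo + m, n)
        r[s0:s1] -= ai * p[s0 - lo : s1 - lo]
        if cfg.clip_negative:
            seg = r[s0:s1]
            neg = np.minimum(seg, 0.0)
            clipped[s0:s1] += neg
            seg -= neg

    order = np.argsort(positions, kind="stable")
    return SparseSpikes(
        positions=np.asarray(positions, dtype=int)[order] if positions else np.empty(0, int),
        amplitudes=np.asarray(amplitudes)[order] if positions else np.empty(0),
        residual=r,
        n_iterations=len(positions),
        clipped=clipped,
        residual_max_history=np.asarray(history),
    )


def spikes_to_signal(spikes: SparseSpikes, length: int) -> np.ndarray:
    """Dense rendering of a spike train (amplitudes accumulated at positions)."""
    x = np.zeros(length)
    if spikes.positions.size == 0:
        return x
    if spikes.positions.min() < 0 or spikes.positions.max() >= length:
        raise ValueError("spike position out of range")
    np.add.at(x, spikes.positions, spikes.amplitudes)
    return x
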