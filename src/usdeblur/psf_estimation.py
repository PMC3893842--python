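"""Blind PSF estimation by homomorphic (cepstral) separation.

In the noise-free frequency domain, ln Y(w) = ln H(w) + ln X(w): the log
spectrum of the measured envelope is the smooth pulse log spectrum plus the
rapidly varying reflectivity term.  Separation is therefore a denoising
problem: the log-magnitude spectrum is wavelet soft-thresholded at Donoho's
universal threshold T = sigma*sqrt(2 ln N), with sigma estimated as
median(|d|)/0.6745 from the finest detail level.  The pulse phase is not
observable from the envelope, so the spectrum is completed under the
minimum-phase assumption via the folded real cepstrum, and the impulse
response is truncated to a compact support and peak-normalized.

Only the log-magnitude path is denoised; the phase comes entirely from the
minimum-phase completion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pywt

from .core import EnvelopeLine, PSFKernel

__all__ = [
    "HomomorphicConfig",
    "log_spectrum",
    "estimate_sigma",
    "universal_threshold",
    "denoise_logspectrum",
    "min_phase_from_logmag",
    "estimate_psf",
]

#: relative floor added to the spectral modulus before the logarithm
LOG_FLOOR = 1e-12

#: fraction of impulse-response energy kept when truncating the support
ENERGY_KEEP = 0.99


@dataclass
class HomomorphicConfig:
    """Tunables of the homomorphic estimator.

    ``wavelet_name`` defaults to 'sym4' (an 8-tap symmetric orthogonal
    wavelet); 5 decomposition levels suffice for smooth pulse log spectra.
    ``denoise`` is a strategy hook ('soft' implemented; the slot exists for
    outlier-resistant variants).
    """

    n_levels: int = 5
    wavelet_name: str = "sym4"
    fft_length: Optional[int] = None
    min_phase: bool = True
    denoise: str = "soft"

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.fft_length is not None and (
            self.fft_length < 2 or self.fft_length & (self.fft_length - 1)
        ):
            raise ValueError("fft_length must be a power of two")


def _next_pow2(n: int) -> int:
    p = 1
    while p < n:
        p *= 2
    return p


def _samples(env: Union[EnvelopeLine, np.ndarray]) -> np.ndarray:
    x = env.samples if isinstance(env, EnvelopeLine) else np.asarray(env, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a one-dimensional envelope")
    return x


def log_spectrum(env: Union[EnvelopeLine, np.ndarray], fft_length: Optional[int] = None) -> np.ndarray:
    """ln |DFT(env)| with a small relative floor to keep the log finite."""
    x = _samples(env)
    if not np.any(x):
        raise ValueError("log spectrum of an all-zero envelope is undefined")
    n = fft_length or x.size
    mod = np.abs(np.fft.fft(x, n))
    return np.log(mod + LOG_FLOOR * mod.max())


def estimate_sigma(finest_detail: np.ndarray) -> float:
    """Robust noise scale: median(|d|) / 0.6745 (Gaussian MAD constant)."""
    d = np.asarray(finest_detail, dtype=float)
    if d.size == 0:
        raise ValueError("empty detail coefficients")
    return float(np.median(np.abs(d)) / 0.6745)


def universal_threshold(sigma: float, n: float) -> float:
    """Donoho's universal threshold T = sigma * sqrt(2 ln n)."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(sigma * np.sqrt(2.0 * np.log(n)))


def denoise_logspectrum(logspec: np.ndarray, cfg: Optional[HomomorphicConfig] = None) -> np.ndarray:
    """Soft-threshold the log spectrum's wavelet details at the universal level.

    sigma is estimated from the finest detail level of the input itself, so
    the threshold adapts per line.  The map is non-expansive on every detail
    coefficient.
    """
    cfg = cfg or HomomorphicConfig()
    x = np.asarray(logspec, dtype=float)
    if x.size % (2**cfg.n_levels) != 0:
        raise ValueError(
            f"length {x.size} not transformable at {cfg.n_levels} levels; pad to a power of two"
        )
    if cfg.denoise != "soft":
        raise NotImplementedError(f"denoise strategy {cfg.denoise!r} not implemented")
    coeffs = pywt.wavedec(x, cfg.wavelet_name, level=cfg.n_levels, mode="periodization")
    sigma = estimate_sigma(coeffs[-1])
    t = universal_threshold(sigma, x.size)
    if t > 0:
        coeffs = [coeffs[0]] + [pywt.threshold(c, t, mode="soft") for c in coeffs[1:]]
    return pywt.waverec(coeffs, cfg.wavelet_name, mode="periodization")[: x.size]


def min_phase_from_logmag(logmag: np.ndarray) -> np.ndarray:
    """Complete a real, even-symmetric log magnitude to a minimum-phase spectrum.

    Real-cepstrum folding: c = IDFT(logmag); double positive-time samples,
    keep c[0] and the Nyquist term once, zero negative time; the spectrum is
    exp(DFT(folded)).  Magnitude is preserved to numerical precision and the
    impulse response is minimum-phase (causal, energy-front-loaded).
    """
    lm = np.asarray(logmag, dtype=float)
    if not np.all(np.isfinite(lm)):
        raise ValueError("log magnitude must be finite")
    n = lm.size
    if n % 2:
        raise ValueError("log magnitude must have even length")
    c = np.fft.ifft(lm).real
    folded = np.zeros(n)
    folded[0] = c[0]
    folded[n // 2] = c[n // 2]
    folded[1 : n // 2] = 2.0 * c[1 : n // 2]
    return np.exp(np.fft.fft(folded))


def estimate_psf(
    env: Union[EnvelopeLine, np.ndarray],
    cfg: Optional[HomomorphicConfig] = None,
    fs: Optional[float] = None,
) -> PSFKernel:
    """Blind pulse-envelope estimate from a measured envelope.

    Chain: log spectrum -> wavelet soft-threshold denoising -> symmetrize ->
    minimum-phase completion -> exp -> IDFT -> truncate to the shortest
    window (centred on the energy peak) holding 99% of the energy ->
    peak-normalize.  The result is invariant to uniform scaling of the input
    (a scale only shifts the log spectrum's DC).
    """
    cfg = cfg or HomomorphicConfig()
    x = _samples(env)
    if not np.any(x):
        raise ValueError("cannot estimate a PSF from an all-zero envelope")
    if fs is None:
        fs = env.fs if isinstance(env, EnvelopeLine) else 20e6
    n_fft = cfg.fft_length or max(_next_pow2(x.size), 2**cfg.n_levels)
    ls = log_spectrum(x, n_fft)
    ds = denoise_logspectrum(ls, cfg)
    # enforce the Hermitian symmetry of a real-signal spectrum: s[k] = s[N-k]
    ds = 0.5 * (ds + np.concatenate(([ds[0]], ds[:0:-1])))
    spec = min_phase_from_logmag(ds) if cfg.min_phase else np.exp(ds)
    h = np.fft.ifft(spec).real
    # centre the energy peak, then keep the shortest odd window with 99% energy
    h = np.roll(h, n_fft // 2 - int(np.argmax(np.abs(h))))
    centre = n_fft // 2
    total = float(np.sum(h**2))
    acc = h[centre] ** 2
    half = 0
    while acc < ENERGY_KEEP * total and half < centre:
        half += 1
        lo, hi = centre - half, centre + half
        acc += h[lo] ** 2
        if hi < n_fft:
            acc += h[hi] ** 2
    kern = h[centre - half : centre + half + 1].copy()
    kern /= kern[int(np.argmax(np.abs(kern)))]
    return PSFKernel(kern, fs=fs, peak_index=int(np.argmax(np.abs(kern))), normalized=True)
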