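"""Container types shared across the deconvolution chain.

The signal model throughout the package is the linear convolution model of
pulse-echo ultrasound: the recorded radio-frequency (RF) trace along one beam
direction is

    y(n) = h(n) * x(n) + u(n)

with ``h`` the system point-spread function (the emitted pulse as blurred by
the transducer/tissue path), ``x`` the tissue reflectivity (sparse: a few
strong scatterers at tissue interfaces) and ``u`` additive white Gaussian
noise standing in for speckle.  The containers below carry the objects of
that model: the RF trace, its detected envelope, the pulse, and the sparse
spike train that deconvolution recovers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["RFLine", "EnvelopeLine", "PSFKernel", "SparseSpikes"]


def _vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class RFLine:
    """A sampled radio-frequency echo trace along one beam direction."""

    samples: np.ndarray
    fs: float = 20e6

    def __post_init__(self) -> None:
        self.samples = _vector(self.samples, "samples")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class EnvelopeLine:
    """Nonnegative envelope |y_a(n)| of an RF line.

    ``source_length`` records the pre-padding length so a pipeline that
    zero-pads to a power of two can crop its outputs back.
    """

    samples: np.ndarray
    fs: float = 20e6
    source_length: Optional[int] = None

    def __post_init__(self) -> None:
        self.samples = _vector(self.samples, "samples")
        if self.samples.size and self.samples.min() < -1e-12 * max(1.0, abs(self.samples).max()):
            raise ValueError("envelope samples must be nonnegative")
        self.samples = np.maximum(self.samples, 0.0)
        if self.source_length is None:
            self.source_length = self.samples.size

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class PSFKernel:
    """The pulse h(n), in RF form (oscillating) or envelope form (bell).

    ``peak_index`` is the index of the largest-magnitude sample; ``normalized``
    flags a unit peak amplitude, the convention all deconvolvers here expect.
    """

    samples: np.ndarray
    fs: float = 20e6
    peak_index: Optional[int] = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.samples = _vector(self.samples, "samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("PSF samples must be finite")
        if self.peak_index is None:
            self.peak_index = int(np.argmax(np.abs(self.samples))) if self.samples.size else 0
        if self.normalized and self.samples.size:
            if abs(np.abs(self.samples).max() - 1.0) > 1e-9:
                raise ValueError("normalized PSF must have unit peak amplitude")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class SparseSpikes:
    """Recovered reflectivity: spike (position, amplitude) pairs plus exit state.

    ``n_iterations`` equals the number of recorded spikes (the sparsity
    coefficient of the greedy algorithm).  ``clipped`` accumulates the
    (negative) residual mass removed by nonnegativity clipping, so that the
    exact accounting  env = sum_i a_i * psf_shifted + clipped + residual
    holds.  ``residual_max_history`` stores the residual maximum at the start
    of each iteration; it is strictly decreasing for generic inputs.
    """

    positions: np.ndarray
    amplitudes: np.ndarray
    residual: np.ndarray
    n_iterations: int
    clipped: Optional[np.ndarray] = None
    residual_max_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.positions.shape != self.amplitudes.shape:
            raise ValueError("positions and amplitudes must align")
        if self.positions.size and np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be sorted")

    def __len__(self) -> int:
        return self.positions.size
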