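"""Envelope detection via the discrete analytic signal.

y_a(n) = y_RF(n) + j H{y_RF(n)} (H the Hilbert transform), envelope
y(n) = |y_a(n)|.  The analytic signal is built the standard FFT way —
zeroing negative frequencies, doubling positive ones, keeping DC (and the
Nyquist bin at even lengths) at unit weight — so the real part of the output
equals the input exactly.  No edge tapering is applied.
"""

from __future__ import annotations

from typing import Union

import numpy as np
from scipy.signal import hilbert

from .core import EnvelopeLine, RFLine

__all__ = ["analytic_signal", "envelope"]


def _validate(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a one-dimensional signal")
    if x.size < 2:
        raise ValueError("signal must have at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    return x


def analytic_signal(rf: Union[RFLine, np.ndarray]) -> np.ndarray:
    """Complex analytic signal of a real RF trace."""
    x = rf.samples if isinstance(rf, RFLine) else rf
    return hilbert(_validate(x))


def envelope(rf: Union[RFLine, np.ndarray]):
    """Envelope |y_a(n)|.

    Returns an :class:`EnvelopeLine` when given an :class:`RFLine`, else a
    plain nonnegative array.
    """
    if isinstance(rf, RFLine):
        env = np.abs(analytic_signal(rf.samples))
        return EnvelopeLine(env, fs=rf.fs, source_length=len(rf))
    return np.abs(analytic_signal(rf))
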