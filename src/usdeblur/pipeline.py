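"""End-to-end per-line processing of 2-D frames.

Each beam line of a frame is processed independently: envelope detection,
zero-padding to the next power of two, blind pulse-envelope estimation,
deconvolution with the chosen method, and cropping back to the original
length.  Per-line failures are collected in a report and the failing lines
zero-filled rather than aborting the frame.  Display output is the usual
log-compressed B-mode map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import numpy as np

from . import baselines
from .core import SparseSpikes
from .envelope import envelope
from .greedy_deconv import GreedyConfig, greedy_deconvolve, normalize_psf_envelope, spikes_to_signal
from .psf_estimation import HomomorphicConfig, estimate_psf

__all__ = ["Frame", "pad_pow2", "log_compress", "deconvolve_frame"]


@dataclass
class Frame:
    """A stack of RF or envelope lines, samples x lines; index 0 at the probe."""

    data: np.ndarray
    fs: float = 20e6
    sound_speed: float = 1540.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.data.ndim != 2 or self.data.shape[1] < 1:
            raise ValueError("frame data must be a (samples, lines) matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("frame data must be finite")

    @property
    def n_lines(self) -> int:
        return self.data.shape[1]

    @property
    def axial_spacing(self) -> float:
        """One-way axial sample spacing in metres, c / fs."""
        return self.sound_speed / self.fs


def pad_pow2(x: np.ndarray) -> np.ndarray:
    """Zero-pad at the tail to the next power of two (identity if already one)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot pad an empty vector")
    n = 1
    while n < x.size:
        n *= 2
    if n == x.size:
        return x.copy()
    out = np.zeros(n)
    out[: x.size] = x
    return out


def log_compress(frame: Union[Frame, np.ndarray], dynamic_range_db: float = 50.0) -> np.ndarray:
    """8-bit log-compressed display map: 20 log10(data/max) clipped to [-DR, 0].

    Rounding is half-up, so the clip boundary maps to 0 and the maximum to 255.
    """
    data = frame.data if isinstance(frame, Frame) else np.asarray(frame, dtype=float)
    if data.min() < 0:
        raise ValueError("log compression expects nonnegative data")
    peak = data.max()
    if peak <= 0:
        raise ValueError("log compression of an all-zero frame is undefined")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(data / peak)
    db = np.clip(db, -dynamic_range_db, 0.0)
    levels = np.floor(255.0 * (db + dynamic_range_db) / dynamic_range_db + 0.5)
    return levels.astype(np.uint8)


def deconvolve_frame(
    frame: Frame,
    method: str = "greedy",
    homomorphic: Optional[HomomorphicConfig] = None,
    greedy_cfg: Optional[GreedyConfig] = None,
    lam: Optional[float] = None,
    psf=None,
    segment_length: Optional[int] = None,
) -> Tuple[Frame, List[Optional[SparseSpikes]], List[Tuple[int, str]]]:
    """Per-line blind deconvolution of a frame.

    Returns the reconstructed frame, the per-line spike trains (``None`` for
    non-greedy methods or failed lines) and a list of (line, message) errors.
    A fixed ``segment_length`` splits each line into windows with their own
    pulse estimates (a simple depth-variant option); the default estimates
    one pulse per whole line.
    """
    n, n_lines = frame.data.shape
    recon = np.zeros_like(frame.data)
    spikes_out: List[Optional[SparseSpikes]] = []
    errors: List[Tuple[int, str]] = []
    for j in range(n_lines):
        try:
            line = frame.data[:, j]
            env = line if np.all(line >= 0) else envelope(line)
            if segment_length is not None and segment_length < n:
                xj = np.zeros(n)
                sp = None
                for s0 in range(0, n, segment_length):
                    seg = env[s0 : s0 + segment_length]
                    xj[s0 : s0 + seg.size] = _deconvolve_line(
                        seg, method, homomorphic, greedy_cfg, lam, psf
                    )[0]
                recon[:, j] = xj
                spikes_out.append(sp)
            else:
                xj, sp = _deconvolve_line(env, method, homomorphic, greedy_cfg, lam, psf)
                recon[:, j] = xj
                spikes_out.append(sp)
        except Exception as exc:  # collected, not raised: one bad line must not kill a frame
            recon[:, j] = 0.0
            spikes_out.append(None)
            errors.append((j, str(exc)))
    out = Frame(recon, fs=frame.fs, sound_speed=frame.sound_speed, meta=dict(frame.meta))
    return out, spikes_out, errors


def _deconvolve_line(env, method, homomorphic, greedy_cfg, lam, psf):
    n = env.size
    env_p = pad_pow2(env)
    psf_env = normalize_psf_envelope(psf if psf is not None else estimate_psf(env_p, homomorphic))
    if method == "greedy":
        spikes = greedy_deconvolve(env_p, psf_env, greedy_cfg)
        keep = spikes.positions < n
        cropped = SparseSpikes(
            positions=spikes.positions[keep],
            amplitudes=spikes.amplitudes[keep],
            residual=spikes.residual[:n],
            n_iterations=int(keep.sum()),
            clipped=spikes.clipped[:n] if spikes.clipped is not None else None,
            residual_max_history=spikes.residual_max_history,
        )
        return spikes_to_signal(cropped, n), cropped
    if method == "wiener":
        return baselines.wiener_deconvolve(env_p, psf_env, lam or baselines.DEFAULT_LAMBDA["wiener"])[:n], None
    if method == "l1":
        return baselines.l1_deconvolve(env_p, psf_env, lam or baselines.DEFAULT_LAMBDA["l1"])[:n], None
    if method == "tv":
        return baselines.tv_deconvolve(env_p, psf_env, lam or baselines.DEFAULT_LAMBDA["tv"])[:n], None
    raise ValueError(f"unknown method {method!r}")
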