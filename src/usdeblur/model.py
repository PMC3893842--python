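"""Model/Results interface for single-line blind deconvolution.

``EnvelopeDeconvolution`` is constructed from data (an RF trace or an
already-detected envelope); ``fit`` runs the chosen deconvolver — greedy
noninverse by default, or one of the regularized baselines — estimating the
pulse blindly when none is supplied, and returns a
:class:`DeconvolutionResults` carrying the spike estimates, residual
diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from . import baselines
from .core import EnvelopeLine, PSFKernel, RFLine
from .envelope import envelope
from .greedy_deconv import GreedyConfig, greedy_deconvolve, normalize_psf_envelope, spikes_to_signal
from .metrics import detect_matches, local_maxima_signal, nmse, resolution_gain
from .psf_estimation import HomomorphicConfig, estimate_psf

__all__ = ["EnvelopeDeconvolution", "DeconvolutionResults"]


class EnvelopeDeconvolution:
    """Sparse-reflectivity deconvolution model for one ultrasound line.

    Parameters
    ----------
    data : array-like, RFLine or EnvelopeLine
        The observed trace.  Plain arrays are interpreted according to
        ``data_domain`` ('rf': envelope is detected first; 'envelope': used
        as-is, must be nonnegative).
    fs : float
        Sampling frequency in Hz (ignored when a typed container carries it).
    psf : PSFKernel or array, optional
        Known pulse; when omitted, ``fit`` estimates it homomorphically from
        the data (blind mode).
    """

    def __init__(self, data, fs: float = 20e6, psf=None, data_domain: str = "rf"):
        if isinstance(data, EnvelopeLine):
            self.env = data
        elif isinstance(data, RFLine):
            self.env = envelope(data)
        else:
            arr = np.asarray(data, dtype=float)
            if data_domain == "rf":
                self.env = envelope(RFLine(arr, fs=fs))
            elif data_domain == "envelope":
                self.env = EnvelopeLine(arr, fs=fs)
            else:
                raise ValueError("data_domain must be 'rf' or 'envelope'")
        self.fs = self.env.fs
        self.psf = psf
        self.nobs = len(self.env)

    @classmethod
    def from_dataframe(cls, df, column: str = "rf", fs: float = 20e6, **kwargs):
        """Build the model from one column of a DataFrame of samples."""
        return cls(df[column].to_numpy(dtype=float), fs=fs, **kwargs)

    def fit(
        self,
        method: str = "greedy",
        lam: Optional[float] = None,
        homomorphic: Optional[HomomorphicConfig] = None,
        greedy: Optional[GreedyConfig] = None,
        max_iter: int = 500,
        tol: float = 1e-6,
    ) -> "DeconvolutionResults":
        """Estimate the sparse reflectivity; returns a results object."""
        if self.psf is not None:
            psf_env = normalize_psf_envelope(
                self.psf if isinstance(self.psf, PSFKernel) else np.asarray(self.psf, float)
            )
            blind = False
        else:
            psf_env = normalize_psf_envelope(estimate_psf(self.env, homomorphic, fs=self.fs))
            blind = True
        y = self.env.samples
        spikes = None
        if method == "greedy":
            spikes = greedy_deconvolve(y, psf_env, greedy)
            x_hat = spikes_to_signal(spikes, y.size)
            positions, amplitudes = spikes.positions, spikes.amplitudes
        elif method == "wiener":
            x_hat = baselines.wiener_deconvolve(y, psf_env, lam or baselines.DEFAULT_LAMBDA["wiener"])
            positions = local_maxima_signal(x_hat)
            positions = positions[x_hat[positions] > 0]
            amplitudes = x_hat[positions]
        elif method in ("l1", "tv"):
            solver = baselines.l1_deconvolve if method == "l1" else baselines.tv_deconvolve
            x_hat = solver(y, psf_env, lam or baselines.DEFAULT_LAMBDA[method],
                           max_iter=max_iter, tol=tol)
            positions = local_maxima_signal(x_hat)
            positions = positions[x_hat[positions] > 0]
            amplitudes = x_hat[positions]
        else:
            raise ValueError(f"unknown method {method!r}")
        return DeconvolutionResults(self, method, psf_env, x_hat, positions, amplitudes,
                                    spikes=spikes, blind=blind)


class DeconvolutionResults:
    """Estimates and diagnostics from a fitted deconvolution."""

    def __init__(self, model, method, psf_env, reflectivity, positions, amplitudes,
                 spikes=None, blind=True):
        self.model = model
        self.method = method
        self.psf_ = psf_env
        self.reflectivity = reflectivity
        self.positions = np.asarray(positions, dtype=int)
        self.amplitudes = np.asarray(amplitudes, dtype=float)
        self.spikes = spikes
        self.blind = blind

    @property
    def params(self) -> np.ndarray:
        """Spike amplitudes (the fitted coefficients)."""
        return self.amplitudes

    @property
    def n_spikes(self) -> int:
        return self.positions.size

    @property
    def residual(self) -> Optional[np.ndarray]:
        return self.spikes.residual if self.spikes is not None else None

    def nmse(self, truth, normalize: bool = True) -> float:
        return nmse(self.reflectivity, truth, normalize=normalize)

    def resolution_gain(self, **kw) -> float:
        return resolution_gain(self.model.env.samples, self.reflectivity, **kw)

    def detected(self, true_positions, tol_samples: int = 2) -> int:
        return detect_matches(self.positions, true_positions, tol_samples)

    def summary(self, truth=None) -> str:
        """Plain-text summary of the fit."""
        lines = [
            "Envelope deconvolution results",
            "=" * 46,
            f"method:            {self.method}",
            f"pulse:             {'blind (homomorphic)' if self.blind else 'user-supplied'}",
            f"n observations:    {self.model.nobs}",
            f"n spikes:          {self.n_spikes}",
            f"resolution gain:   {self.resolution_gain():.3f}",
        ]
        if self.residual is not None:
            lines.append(f"residual max:      {self.residual.max():.3e}")
        if truth is not None:
            lines.append(f"nMSE vs truth:     {self.nmse(truth):.4f}")
        if self.n_spikes:
            lines.append("-" * 46)
            lines.append("  position     depth (mm)    amplitude")
            spacing = self.model.env.fs
            for p, a in list(zip(self.positions, self.amplitudes))[:20]:
                depth_mm = 1e3 * p * 1540.0 / spacing
                lines.append(f"  {p:8d}    {depth_mm:9.2f}    {a:9.4f}")
            if self.n_spikes > 20:
                lines.append(f"  ... ({self.n_spikes - 20} more)")
        return "\n".join(lines)

    def plot(self, ax=None, truth=None):
        """Envelope, recovered spikes and (optionally) the true reflectivity."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        env = self.model.env.samples
        ax.plot(env, color="0.6", lw=0.8, label="envelope")
        ax.stem(self.positions, self.amplitudes, linefmt="C0-", markerfmt="C0o",
                basefmt=" ", label=f"{self.method} spikes")
        if truth is not None:
            truth = np.asarray(truth, dtype=float)
            pos = np.nonzero(truth)[0]
            ax.stem(pos, truth[pos], linefmt="C3--", markerfmt="C3x", basefmt=" ",
                    label="truth")
        ax.set_xlabel("sample")
        ax.set_ylabel("amplitude")
        ax.legend(loc="upper right", fontsize=8)
        return ax
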