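# Methods

## Signal model and scope

All processing is per beam line.  The measured RF trace is modelled as
`y = h ⊗ x + u`: linear convolution of a depth-invariant pulse `h` with a
sparse nonnegative reflectivity `x`, plus white Gaussian noise `u`.  The
package operates on the *envelope* of `y` (modulus of the FFT analytic
signal), which removes the carrier and sidesteps pulse-phase estimation.
Depth-variant blur is out of scope except for a simple fixed-window
`segment_length` option in the frame pipeline that re-estimates the pulse
per segment.

## Synthetic data generator

The simulator reproduces a standard desk-scale evaluation setup:

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 512 | line length; with `fs` and `c` gives a 3.94 cm one-way span |
| `fs` | 20 MHz | sampling frequency |
| `f0` | 3.2 MHz | pulse centre frequency |
| `n_periods` | 3 | sinusoid periods inside the pulse's Gaussian window (3–4 typical) |
| `snr_db` | 25 | realized (not expected) SNR of the added white noise |
| `density` | 0.02 | fraction of samples carrying a scatterer (0.02/0.05/0.10 studied) |
| `laplace_scale` | 1 | scale of the Laplacian amplitude law |
| `sound_speed` | 1540 m/s | standard soft-tissue value |

The RF pulse is `A·exp[−(ωt/(Nπ))²]·sin(ωt)` with `ω = 2πf0`, sampled on the
smallest odd support where the Gaussian window exceeds 10⁻³ of its peak
(51 samples at the defaults; the formula has infinite support and some
truncation rule is needed).  Reflectivity amplitudes are |Laplace(0, b)|
draws at uniformly random positions: envelope-domain reflectivity is
nonnegative, and b cancels in normalized metrics, so b = 1.  Noise is drawn
Gaussian and rescaled so the realized power ratio equals the requested SNR
exactly, which makes statistical tests tight.  Convolution is 'same'-mode
with the pulse centre on the scatter index so ground-truth positions stay in
register with the blurred line.  Frames derive per-column seeds as
`seed + column`.

What the generator does *not* emulate: diffraction, focusing, frequency-
dependent attenuation, depth-variant pulses, and genuinely multiplicative
speckle statistics.  Tests passing on these signals therefore demonstrate
algorithmic correctness under the stated model, not clinical performance.
A consequence that matters for interpreting the benchmark numbers: because
the simulation is coherent RF convolution, pulses from scatterers closer
than roughly the pulse width interfere, and the envelope peak of a merged
cluster shifts by several samples.  Any position-scored metric on such
clusters degrades for *every* deconvolver, which bounds attainable detection
counts at high density (see Limitations).

## Blind PSF estimation

`estimate_psf` chains: FFT log-magnitude (with a relative floor of
10⁻¹² × the spectral maximum before the log) → 5-level `sym4` wavelet
soft-thresholding at the universal threshold, σ taken from the finest
detail level of the same log spectrum → Hermitian symmetrization →
minimum-phase completion by folding the real cepstrum (double positive
time, keep the zero and Nyquist terms once, zero negative time) →
exponential and inverse FFT → truncation to the shortest peak-centred odd
window holding 99% of the energy → peak normalization.  Only the
log-magnitude is denoised; the phase comes entirely from the minimum-phase
assumption.  The estimate is invariant to uniform scaling of the input (a
scale shifts only the spectral DC).

Choices left open by the general method and fixed here: the wavelet is an
8-tap symmetric orthogonal one (`sym4`; the family is second-order for
smooth log spectra and configurable), the denoising strategy slot accepts
only plain soft thresholding (an outlier-resistant variant is a documented
extension hook), and the FFT length is the next power of two.

`normalize_psf_envelope` converts any kernel to the unit-peak nonnegative
envelope form the greedy loop expects.  Genuinely oscillating RF pulses
(minimum below −0.1 × maximum) are demodulated through the analytic signal;
quasi-envelope kernels with small negative ripple are clipped instead — the
analytic envelope of an already-lowpass bell acquires heavy Hilbert tails
that would artificially widen it by nearly a factor two.

## Greedy deconvolution

Exit level `k = 0` (extracts the maximum number of reflectors), argmax ties
break to the lowest index, the shifted kernel is truncated at the signal
edges (no circular wrap), and negative residual samples are clipped to zero
by default (`clip_negative=False` is available, since subtraction with an
imperfect estimated kernel can overshoot locally).  The recorded spike
amplitude is the residual value at the pick, preserving the envelope
amplitude scale.  With clipping and `k = 0` each iteration permanently
zeroes its argmax sample, giving the ≤ N termination bound; the clipped
mass is tracked so that `envelope = Σ aᵢ·p(·−nᵢ) + clipped + residual`
holds exactly.

## Regularized baselines

Wiener `X̂ = H̄Y/(|H|² + λ)` in closed form; ℓ1 by ISTA (step 1/L, L the
squared spectral norm); TV by proximal gradient with Condat's exact 1-D TV
prox.  The convolution operator is circulant after power-of-two
zero-padding, which diagonalizes it and enables the dense-algebra oracle
tests.  Default weights λ = 0.08 / 0.2 / 0.14 are the standard empirical
settings for this comparison and are *not* auto-tuned.  They presuppose an
operator of unit gain: the kernel is internally rescaled to unit area
(`kernel_norm='area'`, equivalent to λ → λ·area² for Wiener and λ → λ·area
for ℓ1/TV), and outputs are returned on the input amplitude scale.  With a
unit-peak envelope kernel instead, |H(0)|² ≈ 130 and these weights would
barely regularize, turning the Wiener output into a noisy quasi-inverse —
measurably wrong qualitative behaviour for this comparison.
`kernel_norm='none'` applies the literal formulas.  Both iterative solvers
guard against objective increase and stop on relative objective change
below `tol` (default 10⁻⁶, cap 500 iterations; the oracle-matching tests
tighten both).

## Metrics

*nMSE* is `‖x̂ − x‖²/‖x‖²` per line, averaged over replicates (mean of
ratios); both signals are max-normalized first by default (`normalize=False`
gives the raw ratio).  *Resolution gain* is the ratio of −3 dB widths of the
peak-normalized autocorrelations of input envelope and output.  The width is
the contiguous central-lobe lag count above 10^(−3/20) ≈ 0.708 (amplitude
convention; a power-mode 0.5 threshold and a linearly interpolated
fractional-lag variant are options).  Counting only the central lobe
matters: secondary autocorrelation peaks at inter-scatterer lags are
structure, not resolution.  *Detection* pairs true and estimated positions
one-to-one, nearest first, within ±2 samples by default; smooth outputs
(Wiener/TV) are first reduced to their positive local maxima (plateaus take
the leftmost point).  The benchmark grid fixes per-replicate sub-seeds as
`seed + 100003·cell + replicate` and shares each simulated line across
methods.

The acceptance report uses density 0.05 for the nMSE/RG conditions (the
study states 2–5% without fixing a value; 0.05 is the midpoint of the range
actually exercised) and the true pulse envelope for the detection counts,
the estimated one for the blind-chain quantities.

## Numerical conventions

Envelope computation keeps the Nyquist bin at unit weight (even lengths) so
the analytic signal's real part equals the input exactly.  The log floor,
the 99% energy truncation, and the 0.1 ripple threshold above are the only
magic constants; each is documented at its definition.  `log_compress` maps
`20·log10(data/max)` clipped to `[−DR, 0]` onto 0–255 with half-up rounding
(display default DR = 50 dB).  Frame processing collects per-line failures
(zero-filling those lines) instead of aborting.

## Known limitations

- Detection counts at high scatterer density are bounded by coherent-
  interference peak shifts (see above): at density 10% the mean matched
  count within ±2 samples plateaus near 25 of 51 regardless of deconvolver
  quality, well below what an incoherent (envelope-additive) reading of the
  model would allow.
- The homomorphic estimate inherits reflectivity-spectrum leakage: per-line
  −3 dB widths of the estimated kernel fluctuate by roughly ±35% around a
  ~+40% mean bias at SNR 21 dB, density 2%.  An outlier-resistant denoising
  stage is the known remedy and is left as the documented extension hook.
- TV deconvolution with the fixed λ = 0.14 mildly sharpens these envelopes
  (resolution gain ≈ 2) rather than smoothing them into wide plateaus; its
  max-normalized nMSE does not improve on the raw envelope, unlike the
  other three methods (the raw-scale error does improve).
- Real-probe effects (aberration, depth-variant blur, scan conversion) are
  untested; the frame pipeline treats lines independently.
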