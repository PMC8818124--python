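# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of pwbeam, in the spirit of a methods appendix: what the code
computes, under which assumptions, and what its passing tests do and do
not demonstrate.

## Data model and conventions

All quantities are SI internally (meters, seconds, Hz, m/s); conversion
to mm/MHz happens only at reporting boundaries. The lateral axis `x` is
centered on the linear array; depth `z` is positive away from the
transducer; images are stored depth-major (z rows, x columns), 0-based.
Per-angle `time_zero_s` anchors sample index 0 to the instant the steered
wavefront crosses the array origin; acquisitions recorded with other
conventions are accommodated by this per-angle offset. ROI files are
declarative YAML in physical coordinates, never pixel indices, so they
bind to any grid.

## Delay-and-sum beamformer

The delay law is the conventional coherent-plane-wave-compounding
geometry for a linear array: transmit τ_tx = (z·cosθ + x·sinθ)/c
(measured from the origin crossing; slightly negative values at shallow
lateral extremes of steered waves are legitimate and permitted), receive
τ_rx = √((x−x_e)² + z²)/c. Angular compounding is coherent: complex
single-angle images are summed before envelope detection.

Numerical choices:

* **Interpolation.** Element traces are sampled by linear interpolation;
  out-of-range contributions are zero. RF traces are first converted to
  their analytic signal (Hilbert transform along the sample axis) and
  mixed down to baseband at the center frequency; interpolation then
  acts on a slowly varying signal and the carrier phase is restored by a
  per-sample rotation exp(+2πi·f_demod·τ). Interpolating the raw
  analytic signal instead loses ~20% of peak amplitude at 4 samples per
  carrier cycle, and that loss varies with the fractional delay.
  Demodulated (IQ) input takes the same path with its own f_demod.
* **Phase rotation.** The rotation uses a 4096-bin one-cycle
  cosine/sine lookup table with linear interpolation (phase error
  < 1e-6 rad), keeping transcendentals out of the compiled inner loop.
* **Precision.** Baseband traces are cached in single precision
  (complex64); accumulation is double. This bounds reproducibility of
  exact-linearity identities at ~1e-6 relative, which the tests reflect.
* **Apodization.** Default is rectangular (all ones) over the full
  aperture — the plain-summation DAS baseline. An optional receive
  f-number excludes elements with |x−x_e| > z/(2·f#).
* **Default grid.** One-third-wavelength isotropic spacing at the
  nominal sound speed when the caller supplies no grid.
* **Envelope detection.** Magnitude of the complex beamsum; because RF
  data ride the analytic-signal path, RF and IQ inputs give consistent
  envelopes (verified to 2% at the point-target peak). Log compression
  is 20·log₁₀(env/max): the image maximum is exactly 0 dB, stored
  values are not clipped (the dynamic-range parameter only controls
  display).

## Global sound-speed estimation

The objective `speckle_brightness(c)` is the mean compounded envelope
over a caller-supplied pixel grid placed in homogeneous speckle, using
all transmissions. Mismatched focusing delays de-cohere the aperture
sum, so the objective peaks at the true global speed.

The estimator is adaptive-moment (Adam) gradient ascent: initial step
10 m/s, exponential step decay 0.9 per iteration, 30 steps, moment
coefficients (0.9, 0.999), ε = 1e-8, gradient by central finite
differences with δ = 0.5 m/s. Because Adam normalizes the gradient by
its running magnitude, each update moves ≈ the current step size uphill
and the iterates are invariant to positive rescaling of the channel
data (a tested property). The returned estimate is the best-observed
speed along the recorded trajectory, not the last iterate, which guards
against overshoot. Speeds are clamped to the physical range
[1000, 2000] m/s. With 30 steps and step 10 m/s the total travel budget
is Σ 10·0.9^k ≈ 96 m/s, which covers the realistic ±90 m/s deviation
from the 1540 m/s nominal assumption.

`grid_search_sound_speed` is the independent brute-force oracle: the
argmax of the same objective over a lattice, ties toward the lowest
speed. The end-to-end tests sweep 1400–1650 m/s at 5 m/s and refine ±5
around the coarse argmax at 1 m/s; the brightness peak is tens of m/s
wide, so the coarse sweep cannot step over it, and the refinement gives
1 m/s final resolution at a quarter of the flat-sweep cost.

Sensitivity caveat, by design of the method: the objective is only as
good as the homogeneity of the chosen speckle region. Region selection
is the caller's responsibility and no automatic selection is attempted.
The estimate can shift by a few m/s with the region and the speckle
realization.

## Image-quality metrics

Local metrics operate on envelope pixels inside ROIs bound to the image
grid (a pixel belongs to an ROI when its center lies inside; binding an
ROI that captures no pixel raises instead of silently averaging nothing).

* contrast = 20·log₁₀(μ₁/μ₂) dB; CNR = (μ₁−μ₂)/√(σ₁²+σ₂²). Both are
  signed and antisymmetric under ROI swap; for a hypoechoic target ROI
  against its background the contrast is negative.
* gCNR = 1 − Σ_bins min(f₁, f₂) with 256 equal-width bins spanning the
  combined min–max of the two ROIs. The joint range makes the measure
  invariant to strictly monotone intensity transforms (exactly so when
  distinct values keep distinct bins). Degenerate input (all values
  identical) returns 0 with a warning.
* Speckle SNR = μ/σ; fully developed (Rayleigh) speckle gives
  √(π/(4−π)) ≈ 1.913.
* FWHM: the envelope maximum inside the point ROI is located on the
  grid (no sub-sample refinement — grid spacing bounds the accuracy,
  which is why the tests assert to within one grid step); lateral and
  axial profiles through the peak are extracted and the width is the
  distance between the two half-maximum crossings nearest the peak,
  found by linear interpolation, reported in mm. A profile that never
  falls below half maximum on one side raises an error naming the side.

Global comparison of a test envelope against a reference on the same
grid: (i) the pixel mask keeps locations where the log-compressed
*reference* is within 40 dB (configurable) of its own maximum — the mask
depends on the reference only and indexes both images; (ii) the test
image is scaled by the closed-form least-squares gain Σxy/Σx² over the
mask, the gain that minimizes the achievable squared error
(equivalently an additive offset in dB); (iii) ℓ1 and ℓ2 are means of
|x−y| and |x−y|² over masked pixels on the linear scale (normalized by
the reference maximum) and on the dB scale (ℓ1-log, ℓ2-log); (iv)
PSNR = 20·log₁₀(dynamic range / RMS dB error), so identical images give
+∞ (reported as an infinity sentinel); (v) ρ is the Pearson correlation
of the masked dB images. Computing ρ and PSNR on the compressed scale
keeps them in the familiar 0–1 / tens-of-dB ranges for speckle imagery.

## Challenge scoring

Each metric is ranked across methods with fractional (average-tie)
ranking — the standard convention, and the one that makes a tie between
two zero-parameter reference beamformers well-defined. Directions are
`higher_better`, `lower_better`, or `closest_to_reference` (rank by
|value − reference|; used for speckle-SNR *preservation* against the
fully compounded reference rather than maximization). The final score
is mean(image-quality ranks) + mean(network-complexity ranks), lower
better. Network complexity enters as a supplied learnable-parameter
count; models are never inspected. `combine_category_ranks` applies the
additive rule directly when per-category ranks are given rather than
recomputed.

## Synthetic phantoms

The simulator is a linear single-scattering forward model: every
scatterer contributes a Gaussian-modulated sinusoid (default 60%
fractional bandwidth at −6 dB) at its round-trip arrival time, computed
with the same plane-wave delay law the beamformer inverts, evaluated on
a dense lookup table over its ±4σ support. White noise can be added at
a level relative to the clean peak. All randomness flows through
explicit seeds; fixed inputs give bit-identical output.

The default rig is a 96-element linear array at one-wavelength pitch
(23.4 mm aperture), 6.25 MHz center frequency, 25 MHz sampling, 75
plane waves spanning ±16°, nominal 1540 m/s. The 75-angle ±16° sequence
matches the dominant plane-wave benchmark configuration. The aperture
width was chosen so that focusing is genuinely sensitive to the assumed
sound speed: with a half-wavelength-pitch 64-element aperture (~8 mm,
f/2.5 at 20 mm depth) the speckle-brightness objective is nearly flat
over ±50 m/s and its argmax wanders tens of m/s from the true speed,
which would make sound-speed estimation meaningless at any accuracy;
the 23 mm aperture produces a sharp, unbiased peak.

Speckle regions draw uniformly positioned scatterers with |N(0,1)|
reflectivities at a density per *compound* resolution cell — pulse-limited
axial extent (c·2.355·σ_t/2) times the compounded lateral beamwidth
λz/(D + 2z·sinθ_max). The default is 20 per cell: Monte-Carlo statistics
of the random phasor sum show the envelope SNR is intrinsically ~3%
below the Rayleigh limit at 10 per cell and ~1.3% below at 20, so 20 is
the smallest density that honestly supports Rayleigh-statistics checks
at the 5% level. Lesions scale reflectivities inside a circle by a
ratio in [0, 1] (0 = anechoic).

What the phantoms emulate: geometric time-of-flight at a configurable
true speed, fully developed speckle, anechoic/hypoechoic circular
lesions, isolated point targets, additive white noise. What they omit:
attenuation and dispersion, element directivity, multiple scattering,
nonlinear propagation, reverberation clutter and heterogeneous
sound-speed maps. Tests passing on these phantoms therefore validate
the *evaluation machinery and geometry*, not robustness to in vivo
artifacts.

## Problem sizes in the test suite

The end-to-end tests run at desk scale: speckle phantoms of ~8×9 mm with
brightness grids of ~6×6 mm at λ/3, lesion phantoms of 12×12 mm, and
scatterer density 10 per cell for the sound-speed and lesion fixtures
(which do not rely on Rayleigh asymptotics) versus the default 20 for
the envelope-statistics checks. Sound-speed recovery is exercised at
1450, 1500, 1540, 1580, and 1620 m/s — spanning the range reported for
real crowd-sourced phantom data — each against the grid-search oracle.

## Known limitations

* Linear arrays only; no phased-array scan conversion, no vendor file
  formats.
* The FWHM peak is not sub-sample refined; resolution estimates are
  quantized to the grid.
* The least-squares gain is the only normalization offered for global
  comparisons (a gain+offset or log-domain fit would be a drop-in
  replacement).
* The speckle-brightness objective assumes a homogeneous ROI; no
  safeguard detects a structured region.
* Scoring operates on supplied metric tables; it does not recompute the
  significance of rank differences.
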