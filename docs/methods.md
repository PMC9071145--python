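# Methods

`perceptqa` measures the perceptual quality of an image-processing algorithm
by *performance*, not by opinion: how much added white noise does the
algorithm render undetectable to an observer in a two-alternative forced
choice (2AFC)? The package implements the full chain — log-Gabor filter
banks, a multiscale threshold denoiser, natural-image surrogate stimuli,
PSNR metrics, and an adaptive-staircase 2AFC simulation with a pluggable
observer model — and this note records the models, parameter choices and
numerical decisions behind each piece.

## Log-Gabor filters

Filters are defined in the Fourier plane in polar coordinates
(f in cycles/image, θ in degrees; angles are degrees at every interface and
radians internally).

**Cartesian-separable family.** The amplitude is the product of a Gaussian on
a log-frequency axis, evaluated along the preferred orientation, and a
Gaussian along the orthogonal Cartesian axis:

    logGab1D(f,θ) = exp( − log2²( f·|cos(θ−θ0)| / f0 ) / (2σ²) ),  σ = 0.424·ω
    orthFunc(f,θ) = exp( − (f·sin(θ−θ0))² / (2η²) )

ω is the spatial-frequency full width at half height in octaves and h the
orientation *half*-width at half height in degrees. η is derived from h by
requiring the 2-D product to equal 0.5 at (f0, θ0+h):

    η = f0·sin(h) · sqrt( 1 / (ln4 − (log2|cos h| / 0.424ω)²) )

This identity is exact by construction and is verified to 1e-9 at continuous
coordinates across a parameter sweep. Because the expression under the root
must stay positive, the family has a maximum orientation bandwidth; the
package determines it by bisection on the sign of `ln4 − k(h)` and the result
tracks the linear law `15·log2(ω) + 45` degrees to within 1° on the open
interval 0.7 < ω < 5 (at exactly ω = 0.7 the true limit is 1.01° above the
line, which is why the law is quoted on the open interval). At ω = 1 the
limit is 44.97°.

The constant 0.424 is the conventional rounded value of σ/FWHH
(exactly 1/(2√(2 ln 2)) = 0.42466). Consequences of the rounding are kept,
not corrected: the radial profile's half-height sits at f0·2^(ω/2) only to
within ~1e-3, while the orientation half-height identity is exact because η
absorbs the same constant.

**Polar-separable family.** Radial term Gaussian in ln(f/f0) with scale
ln(ω), angular term Gaussian in the wrapped angular difference with scale h
(radians), completed by the 180°-rotated lobe. Note the radial
parameterisation uses the natural-log form with scale ln(ω) — the form used
by the reference implementation — so ω is not exactly an octave FWHH for this
family; this is a deliberate, documented choice between two published
variants of the definition.

**Degenerate points.** The amplitude is defined as 0 (its continuous limit)
wherever `f·|cos(θ−θ0)| = 0`, and is forced to exactly 0 at DC so every
kernel is D.C.-balanced: kernel pixel sums are below 1e-8 of the peak for all
phases and both families.

**Phase and kernels.** The requested phase is written directly into the phase
spectrum: the half-plane on the filter's positive axis gets `exp(−iφ)`, the
opposite half its conjugate. φ = 0 gives the even-symmetric (cosine-phase)
kernel, φ = 90 the odd-symmetric one. Kernels are peak-normalised
individually; a bank-level rescale to the global peak is available for
exporting balanced kernel sets. The Nyquist row/column of an even grid
aliases ±Nyquist, so sampled spectra are not perfectly Hermitian there; the
filter amplitude on those lines is negligible and the imaginary residue of a
kernel is required to stay below 1e-4 of its peak.

**Grid convention.** DC sits at 1-based index (size+2)/2 on both axes (0-based
size//2), matching `fftshift` of the standard FFT layout; u varies along
columns, v along rows, f = √(u²+v²), θ = atan2(v, u).

## Multiscale denoiser

**Bank layout.** Default: 6 scales in octave steps, ω = 1.43 octaves for
every filter, orientation channels evenly spaced over 180° with
`round(180/FWHH)` channels per scale (4, 8 or 16 for FWHH 45°, 22.5°,
11.25°; the experimental bandwidths are full widths, halved to h at the
filter interface — a `width_convention` flag makes the choice explicit).
The finest centre frequency defaults to Nyquist/√2 so the six octave-spaced
scales span the full spectrum; any `base_f0` below Nyquist may be set
instead.

**Coverage.** Narrow orientation channels cannot tile the corners of the
Fourier plane (beyond the Nyquist circle their tails underflow to zero), so
the bank adds an isotropic raised-cosine highpass "corner cap" as an ordinary
*thresholdable* element. This matters for denoising: roughly a fifth of the
energy of white pixel noise lives beyond the Nyquist circle, and leaving it
in a protected residual would cap the achievable PSNR gain at ~6.7 dB. A
protected (never-thresholded) highpass residual remains available by
configuration for analysis uses; the protected raised-cosine *lowpass*
residual below the coarsest scale always carries DC and the deepest
frequencies.

**Analytic coefficients and exact inversion.** Each oriented filter is stored
as a single positive-frequency lobe, so coefficient planes are complex with
magnitude = local contrast envelope and phase = local phase. The lobe mask is
defined pairwise — keep pixel k when `uft(k) ≥ uft(−k)`, where uft is the
frequency component along the filter's axis — because the Nyquist row/column
maps to itself under frequency negation and a naive `uft > 0` mask leaves the
self-conjugate Nyquist pixel uncovered. Reconstruction multiplies each
coefficient spectrum by its filter again, Hermitian-symmetrises the sum
(Y + conj(Y∘neg)), adds the residual terms and divides pointwise by
D = Σ(M² + M²∘neg) + L² (+H²): a self-inverting normalised frame. The
un-thresholded round trip is exact to machine precision (~1e-15 relative
RMS, against a contract of 1e-3), and D's non-DC minimum is ~0.4 for all
default configurations (construction fails if it ever drops below 1e-6).

**Thresholding.** Hard: coefficients with |c| < T are zeroed. Soft:
magnitudes shrink by T (floor 0), phases preserved. Residual bands are never
thresholded. Thresholds are amplitudes in coefficient-magnitude units —
a scalar, per scale, or per element — but the practical parameterisation is
noise-scaled: T_j = t · σ_noise · gain_j, with gain_j the subband's
coefficient RMS under unit-variance white noise (computable in closed form
from the filter spectrum). A single *absolute* scalar across scales is
supported but ineffective, since subband noise RMS spans more than an order
of magnitude across six octaves.

**Threshold optimisation.** For each noise level, seeded noise is added to a
set of clean images, each noisy image is decomposed once, and mean PSNR is
measured over a 9-point geometric grid of noise-relative thresholds
t ∈ [0.7, 5.6] (optima in practice fall at t ≈ 2–3.5). A degree-4 polynomial
in log2(t) is fitted and maximised on the grid hull; if the fitted optimum
measures worse than the best grid point by more than 0.2 dB (non-concave
fit), the best grid point is used and the fallback is logged. Grid, degree
and tolerance are configurable.

## Stimuli

**Surrogate natural images.** Experiments run on synthetic images that
reproduce the second-order statistics reported for calibrated
natural-image sets: amplitude spectrum exactly ∝ f^α with α = −1.45 by
default, uniformly random Hermitian phases, mean level 0.5, RMS contrast set
exactly in dB (C_dB = 20·log10 of the pixel standard deviation as a
percentage; 21 dB ≈ 11.2% by default). Requests that would clip the unit
interval are rejected with the maximum achievable contrast; the set generator
skips such seeds deterministically. Note the headroom limit: at mean 0.5 a
25 dB contrast leaves only 2.8σ of range, so high contrasts are realisable
only for steep (smooth) spectra. What the surrogates do *not* emulate:
phase structure (edges, objects), grey-level skew (an optional pointwise
nonlinearity is deliberately omitted), and spatial nonstationarity. Tests
passing on surrogates therefore validate the machinery and its second-order
behaviour, not performance on real photographs.

**Preprocessing of real images** mirrors the stimulus pipeline: lower-right
256×256 crop, greyscale, D.C.-balance to mean 0.5, contrast halved to leave
noise headroom. The spectral slope is estimated from the orientation-pooled
amplitude spectrum in 100 equal frequency bins up to Nyquist, least-squares
on log-log with the DC and lowest bins excluded; image sets can be screened
by slope (default retention bounds [−2.2, −0.8], a configurable choice since
published screening bounds are not stated).

**Noise and windowing.** Added noise is zero-mean Gaussian pixel noise
("white pixel noise" made concrete) with std 10^(C_dB/20)/100; outputs are
clipped to [0,1] with the clipped fraction recorded (zero in the intended
operating range). Stimuli are windowed by a circular raised cosine about the
mean level — plateau, cosine ramp (default 32 px), envelope 0.5 at diameter
240 px on a 256 grid (0.9375·size at other sizes).

## Quality metrics

MSE is the pixel mean squared difference on the 0–1 scale and
PSNR = 10·log10(L²/MSE) with L = 1. PSNR of identical images is an explicit
error, not a number. PSNR-vs-noise curves average PSNR per image then across
images.

**Slope convention.** For pure added noise, MSE equals the noise variance, so
PSNR = 40 − C_dB and the raw regression slope is −1 dB/dB. The literature
this package follows quotes the rate on a convention in which the contrast
axis carries twice the dB rate of the PSNR axis (PSNR being a power-form
decibel, contrast an amplitude-form one), making the canonical noisy-image
slope −1/2. `PsnrCurve.slope` reports that conventional value (= raw/2) and
`PsnrCurve.slope_raw` the untransformed coefficient. With per-level optimal
hard thresholds the denoised curve is flatter: slope ≈ −0.21 (convention
units) over the 9–27 dB mid-range on 20 surrogate images, against ≈ −0.49
for the noisy condition; the denoised fit range (default 9–27 dB, where the
curve is roughly linear) is recorded in the result.

## Simulated 2AFC experiment

**Task.** Two different images per trial (same-image pairing available as a
flag), one with added noise at the staircase's level; in denoising conditions
both then pass through the denoiser with that level's precomputed optimal
threshold; both are windowed; the observer reports the interval with the
noise. Presentation timing of a human experiment (100 ms exposures, 400 ms
ISI) has no analogue here and is not modelled.

**Staircases.** Two randomly interleaved 3-down-1-up staircases in exactly
3 dB steps (a factor √2 in contrast), converging near the 79.4%-correct
point (0.5^(1/3)); block length defaults to 100 trials (configurable), with
every image used at most once per block. Termination is by trial count — a
fixed-count rule is adopted since a universal stopping rule is not part of
the design.

**Observer model.** Humans cannot be packaged, so the observer is an explicit
interface: statistic per image + zero-mean Gaussian internal noise + "pick
the larger" (ties → interval 1, reachable only with zero internal noise).
The default statistic is the *rectified peak high-frequency response*:
max(peak |highpass-band response| − floor, 0), with a raised-cosine highpass
above a cutoff (default 0.25·size cycles/image, below the finest filter band)
and the floor set to the clean-pool mean during calibration — an absolute
visibility threshold on isolated high-frequency events. The rationale: a
threshold denoiser's visible failures are *localized* kernel-shaped blobs
whose amplitude grows with the threshold (∝ t·σ), so a peak statistic rises
monotonically with noise level in both the baseline and the denoised
conditions. A global energy statistic (available as
`statistic_name="energy_fraction"`) is *not* monotone in the denoised
condition — the PSNR-optimal threshold grows with σ and the number of
surviving noise coefficients falls as exp(−t²), so total artefact energy
shrinks even as individual artefacts grow — which stalls the staircase;
this was measured, and is why the peak statistic is the default.

**Calibration.** The floor and the internal-noise SD are set once per
experiment from the clean image pool: the SD solves
Φ(Δ/√(v_clean + v_noisy + 2·SD²)) = 0.75 at a configurable baseline target
level (default 9 dB), where Δ and the variances are measured statistics with
and without noise at that level. Per-condition observers share the
calibration and differ only in their decision-noise seed.

**Psychometric fits.** Maximum-likelihood cumulative log-Gaussian on the dB
axis (equivalently log-Gaussian in linear contrast):
p(x) = γ + (1−γ−λ)·Φ((x−μ)/s) with guess rate γ = 0.5 fixed by the 2AFC
design and lapse rate λ fixed at 0.01 for fitting stability. Fits are
independent per block (no slope sharing across conditions). The threshold is
the exact 75%-correct level of the fitted function. Degenerate data (fewer
than two levels, or all responses identical) raise an explicit
non-convergence error. Parameter recovery on synthetic data with
staircase-like trial placement: |bias| < 0.5 dB and ~90% of replicates
within 1 dB at 400 trials.

**Threshold elevation** — the package's quality measure — is the treated
minus baseline 75% threshold in dB; thresholds are averaged across block
repetitions in dB (log units). With the default observer the simulated
elevations are large (≈ +10 dB at the reduced test scale) and statistically
indistinguishable across the six bank variants (2 families × 3 orientation
bandwidths); the *magnitude* is a property of the observer model, which is
far less sensitive to structured artefacts than human vision, so only the
sign and the variant-equivalence are meaningful analogues of the human
result.

## Problem sizes and determinism

Default study conditions are 256×256 images, 6 scales, pools of ~220 images
and 4 repetitions. The packaged test suite exercises the experiment at a
reduced size chosen to keep the whole suite fast — 128×128 images, 5 scales,
50-trial blocks, a 110-image pool, 2 repetitions, 2 calibration images —
and the slope analyses at 10–20 images of 256×256. Every random quantity
draws from a generator seeded by a global seed plus a stable operation label
(SHA-256 → SeedSequence), so experiments are bitwise reproducible; identical
configs and seeds give byte-identical outputs.

## Known limitations

- Surrogate images lack phase structure; absolute thresholds and elevations
  will differ on real photographs.
- The observer model is a single-statistic energy detector; it underweights
  blur and mid-frequency structure relative to human vision, inflating
  threshold elevations.
- The polar family's ω is not an octave FWHH (natural-log parameterisation).
- The corner cap is isotropic, so orientation information above the finest
  oriented scale is not resolved (it is thresholded as one band).
- Hard/soft thresholding acts on coefficient magnitudes (phase-preserving);
  signed-real-response thresholding is not implemented.
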