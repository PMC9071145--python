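"""Stimulus preparation: preprocessing, 1/f synthesis, noise, windowing.

Natural greyscale photographs have amplitude spectra that fall off roughly as
``f**alpha`` with ``alpha`` around -1.45 and (after contrast halving) an RMS
contrast near 21 dB.  :func:`synth_natural_image` builds surrogate images with
exactly those second-order statistics (power-law amplitude spectrum, uniform
random phases), so experiments can run without any external image database.

Conventions: images live on the unit interval with mean level 0.5; RMS
contrast in dB is ``20*log10(C_RMS%)`` where ``C_RMS%`` is the pixel standard
deviation expressed as a percentage of the unit range (so 1% contrast = 0 dB,
10% = 20 dB).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageStim",
    "NoiseCondition",
    "SpectralStats",
    "ClippingError",
    "preprocess",
    "spectral_slope",
    "spectral_stats",
    "synth_natural_image",
    "synth_image_set",
    "add_white_noise",
    "noise_std_from_db",
    "contrast_db",
    "apply_window",
    "screen_image_set",
]

log = logging.getLogger("perceptqa.stimuli")


class ClippingError(ValueError):
    """Requested contrast cannot be realised within [0, 1] at mean 0.5."""


def noise_std_from_db(c_db: float) -> float:
    """Pixel standard deviation on the 0-1 scale for an RMS contrast in dB."""
    return 10.0 ** (c_db / 20.0) / 100.0


def contrast_db(pixels: np.ndarray) -> float:
    """RMS contrast in dB (20*log10 of the pixel std as a percentage)."""
    sd = float(np.std(pixels))
    if sd <= 0:
        raise ValueError("image has zero contrast")
    return 20.0 * math.log10(100.0 * sd)


@dataclass(frozen=True)
class ImageStim:
    """Unit-interval greyscale stimulus with provenance."""

    pixels: np.ndarray = field(repr=False)
    mean_level: float = 0.5
    provenance: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def rms_contrast_db(self) -> float:
        return contrast_db(self.pixels)


@dataclass(frozen=True)
class NoiseCondition:
    """White-noise level (dB re 1% RMS contrast) plus the seed that fixes it."""

    contrast_db: float
    seed: int

    @property
    def std(self) -> float:
        return noise_std_from_db(self.contrast_db)


@dataclass(frozen=True)
class SpectralStats:
    alpha: float
    rms_contrast_db: float
    n_bins: int = 100


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(raw_image: np.ndarray, crop: int = 256, mean_level: float = 0.5) -> ImageStim:
    """Crop, greyscale, D.C.-balance and contrast-halve a raw image.

    The ``crop`` × ``crop`` patch is taken from the lower-right corner.  The
    result has mean exactly ``mean_level`` and half the input's RMS contrast,
    leaving headroom for added noise.
    """
    arr = np.asarray(raw_image)
    if arr.ndim == 3:
        from skimage.color import rgb2gray

        arr = rgb2gray(arr[..., :3])
    elif arr.ndim != 2:
        raise ValueError(f"expected a 2-D or RGB image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    if arr.shape[0] < crop or arr.shape[1] < crop:
        raise ValueError(
            f"input {arr.shape} smaller than the {crop}x{crop} crop"
        )
    patch = arr[-crop:, -crop:]
    out = mean_level + (patch - patch.mean()) / 2.0
    return ImageStim(pixels=out, mean_level=mean_level,
                     provenance={"origin": "file", "crop": crop})


# ---------------------------------------------------------------------------
# Spectral statistics
# ---------------------------------------------------------------------------

def _radial_freq(size: int) -> np.ndarray:
    fr = np.fft.fftfreq(size) * size
    fx, fy = np.meshgrid(fr, fr)
    return np.hypot(fx, fy)


def spectral_slope(stim: ImageStim | np.ndarray, n_bins: int = 100) -> float:
    """Spectral slope ``alpha``: log amplitude vs log frequency, pooled over
    orientation in ``n_bins`` equal frequency bins up to Nyquist.

    The DC bin is removed by balancing and the lowest bin is excluded from the
    least-squares fit (bins 2..n_bins).
    """
    pixels = stim.pixels if isinstance(stim, ImageStim) else np.asarray(stim)
    balanced = pixels - pixels.mean()
    if not np.any(balanced):
        raise ValueError("all-zero (constant) image: spectral slope undefined")
    size = pixels.shape[0]
    amp = np.abs(np.fft.fft2(balanced))
    f = _radial_freq(size)
    edges = np.linspace(0.0, size / 2.0, n_bins + 1)
    idx = np.digitize(f.ravel(), edges) - 1
    ok = (idx >= 0) & (idx < n_bins) & (f.ravel() > 0)
    sums = np.bincount(idx[ok], weights=amp.ravel()[ok], minlength=n_bins)
    counts = np.bincount(idx[ok], minlength=n_bins)
    centres = 0.5 * (edges[:-1] + edges[1:])
    use = counts > 0
    use[0] = False  # lowest bin excluded from the fit
    x = np.log10(centres[use])
    y = np.log10(sums[use] / counts[use])
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def spectral_stats(stim: ImageStim, n_bins: int = 100) -> SpectralStats:
    return SpectralStats(alpha=spectral_slope(stim, n_bins),
                         rms_contrast_db=stim.rms_contrast_db,
                         n_bins=n_bins)


# ---------------------------------------------------------------------------
# Synthesis
# ---------------------------------------------------------------------------

def synth_natural_image(size: int = 256, alpha: float = -1.45,
                        contrast_db: float = 21.0, seed: int = 0,
                        mean_level: float = 0.5) -> ImageStim:
    """Synthesise a natural-image surrogate.

    The amplitude spectrum is exactly ``f**alpha`` (zero at DC) with uniformly
    random Hermitian-symmetric phases; the pixel standard deviation is scaled
    to the requested RMS contrast and the mean set to ``mean_level``.

    Raises
    ------
    ClippingError
        If the requested contrast would push pixels outside [0, 1]; the
        message reports the maximum achievable contrast for this seed.
    """
    if not (-3.0 <= alpha <= 0.0):
        raise ValueError(f"alpha={alpha} outside the supported range [-3, 0]")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((size, size))
    phases = np.angle(np.fft.fft2(white))  # Hermitian-antisymmetric by construction
    f = _radial_freq(size)
    amp = np.zeros_like(f)
    nz = f > 0
    amp[nz] = f[nz] ** alpha
    field_ = np.fft.ifft2(amp * np.exp(1j * phases)).real
    field_ -= field_.mean()
    target_std = noise_std_from_db(contrast_db)
    field_ *= target_std / field_.std()
    headroom = min(mean_level, 1.0 - mean_level)
    max_dev = float(np.abs(field_).max())
    if max_dev > headroom:
        achievable = contrast_db + 20.0 * math.log10(headroom / max_dev)
        raise ClippingError(
            f"contrast {contrast_db} dB requires clipping for seed {seed}; "
            f"max achievable contrast is {achievable:.2f} dB"
        )
    return ImageStim(
        pixels=field_ + mean_level, mean_level=mean_level,
        provenance={"origin": "synthetic", "alpha": alpha,
                    "contrast_db": contrast_db, "seed": seed},
    )


def synth_image_set(n: int, size: int = 256, alpha: float = -1.45,
                    contrast_db: float = 21.0, seed: int = 0) -> list[ImageStim]:
    """Generate ``n`` surrogate images from a deterministic seed stream.

    Seeds that would require clipping are skipped (and logged), so the set is
    reproducible from ``seed`` alone.
    """
    from .config import derive_seed

    images: list[ImageStim] = []
    k = 0
    while len(images) < n:
        child = derive_seed(seed, "synth-image", k)
        k += 1
        try:
            images.append(synth_natural_image(size, alpha, contrast_db, child))
        except ClippingError as exc:
            log.info("skipping clipped draw %d: %s", k - 1, exc)
        if k > 10 * n + 100:
            raise RuntimeError("too many clipped draws; lower the contrast")
    return images


# ---------------------------------------------------------------------------
# Noise and windowing
# ---------------------------------------------------------------------------

def add_white_noise(stim: ImageStim, condition: NoiseCondition) -> ImageStim:
    """Add zero-mean Gaussian pixel noise at the condition's RMS contrast.

    The output is clipped to [0, 1]; the clipped fraction is recorded in the
    provenance (and is zero in the intended operating range).
    """
    rng = np.random.default_rng(condition.seed)
    noise = rng.normal(0.0, condition.std, stim.pixels.shape)
    raw = stim.pixels + noise
    clipped = np.clip(raw, 0.0, 1.0)
    clip_fraction = float(np.mean(raw != clipped))
    if clip_fraction > 0:
        log.debug("noise at %.1f dB clipped %.3f%% of pixels",
                  condition.contrast_db, 100 * clip_fraction)
    prov = dict(stim.provenance)
    prov.update({"noise_db": condition.contrast_db,
                 "noise_seed": condition.seed,
                 "clip_fraction": clip_fraction})
    return ImageStim(pixels=clipped, mean_level=stim.mean_level, provenance=prov)


def apply_window(stim: ImageStim, fwhh_px: float = 240.0,
                 ramp_px: float = 32.0) -> ImageStim:
    """Multiply contrast by a circular raised-cosine envelope.

    The envelope is 1 on a central plateau, falls along a cosine ramp of
    length ``ramp_px`` and passes 0.5 at diameter ``fwhh_px``.  It modulates
    contrast about the mean level, not luminance.
    """
    size = stim.size
    if fwhh_px > size:
        raise ValueError(f"window FWHH {fwhh_px} exceeds image size {size}")
    half = fwhh_px / 2.0
    r_plateau = half - ramp_px / 2.0
    centre = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(xx - centre, yy - centre)
    t = np.clip((r - r_plateau) / ramp_px, 0.0, 1.0)
    envelope = 0.5 + 0.5 * np.cos(np.pi * t)
    out = stim.mean_level + envelope * (stim.pixels - stim.mean_level)
    prov = dict(stim.provenance)
    prov.update({"window_fwhh_px": fwhh_px, "window_ramp_px": ramp_px})
    return ImageStim(pixels=out, mean_level=stim.mean_level, provenance=prov)


def screen_image_set(stims, slope_bounds=(-2.2, -0.8)):
    """Split a stimulus set by spectral slope.

    Returns ``(retained, rejected)``; an image is retained iff its slope lies
    within ``slope_bounds`` (inclusive).
    """
    lo, hi = slope_bounds
    if lo > hi:
        raise ValueError(f"slope bounds must be ordered, got {slope_bounds}")
    retained, rejected = [], []
    for stim in stims:
        (retained if lo <= spectral_slope(stim) <= hi else rejected).append(stim)
    log.info("screened %d images: %d retained, %d rejected",
             len(retained) + len(rejected), len(retained), len(rejected))
    return retained, rejected
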