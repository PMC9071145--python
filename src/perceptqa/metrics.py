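"""Error statistics: MSE, PSNR, and PSNR-versus-noise-contrast curves.

PSNR is ``10*log10(L**2 / MSE)`` with dynamic range ``L = 1`` for unit-interval
images.  Noise contrast is quoted in amplitude decibels,
``C_dB = 20*log10(C_RMS%)``.

Slope convention.  Because the PSNR axis uses the power form of the decibel
(factor 10 on ``log10(L^2/MSE)``) while the contrast axis uses the amplitude
form (factor 20), the perceptual-denoising literature quotes the rate of PSNR
loss on a convention in which the contrast axis carries twice the dB rate of
the PSNR axis: under it, ideal added white noise costs 1 dB of PSNR per 2 dB
of noise contrast (slope -1/2).  :class:`PsnrCurve` reports that conventional
value as ``slope`` and also stores the unscaled regression coefficient
``slope_raw`` (d mean-PSNR / d C_dB, -1 for ideal white noise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import derive_seed
from .stimuli import ImageStim, NoiseCondition, add_white_noise

__all__ = [
    "QualityScore",
    "PsnrCurve",
    "IdenticalImagesError",
    "mse",
    "psnr",
    "quality_score",
    "psnr_curve",
    "threshold_to_psnr",
]

log = logging.getLogger("perceptqa.metrics")


class IdenticalImagesError(ValueError):
    """MSE is zero: PSNR is not a number for identical images."""


def _pixels(im) -> np.ndarray:
    return im.pixels if isinstance(im, ImageStim) else np.asarray(im, dtype=float)


def mse(image_o, image_n) -> float:
    """Mean squared error between two equal-shape images on the 0-1 scale."""
    a, b = _pixels(image_o), _pixels(image_n)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def psnr(image_o, image_n, L: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB, ``10*log10(L**2/MSE)``."""
    m = mse(image_o, image_n)
    if m == 0:
        raise IdenticalImagesError("images are identical; PSNR is unbounded")
    return float(10.0 * np.log10(L * L / m))


@dataclass(frozen=True)
class QualityScore:
    mse: float
    psnr_db: float
    L: float = 1.0
    n: int = 0


def quality_score(image_o, image_n, L: float = 1.0) -> QualityScore:
    m = mse(image_o, image_n)
    return QualityScore(mse=m, psnr_db=psnr(image_o, image_n, L), L=L,
                        n=int(_pixels(image_o).size))


# ---------------------------------------------------------------------------
# PSNR curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsnrCurve:
    """Mean PSNR over an image set at each added-noise contrast level."""

    noise_levels_db: tuple
    mean_psnr_db: tuple
    sd_psnr_db: tuple
    n_images: int
    condition: str
    slope: float
    slope_raw: float
    fit_range_db: tuple
    thresholds: tuple = field(default=())  # per-level t* for denoised curves


def psnr_curve(images, levels_db, bank=None, mode: str = "hard",
               t_grid=None, seed: int = 0, fit_range_db=None) -> PsnrCurve:
    """Mean PSNR vs noise level, optionally after denoising.

    For each level, seeded white noise is added to every image.  Without a
    ``bank`` the curve scores the noisy images directly; with one, the
    PSNR-optimal noise-scaled threshold is selected per level (polynomial fit
    over ``t_grid``) and the denoised images are scored.  The regression range
    for the slope defaults to the full level range for the noisy condition and
    9-27 dB (the roughly linear mid-range) for the denoised condition.
    """
    from .denoise import optimize_threshold

    levels = [float(l) for l in levels_db]
    if len(levels) < 4:
        raise ValueError("need at least 4 noise levels for a slope")
    stims = [im if isinstance(im, ImageStim) else ImageStim(pixels=np.asarray(im, float))
             for im in images]
    means, sds, tstars = [], [], []
    for level in levels:
        noisy = [add_white_noise(im, NoiseCondition(level, derive_seed(seed, "curve-noise", level, i)))
                 for i, im in enumerate(stims)]
        if bank is None:
            vals = np.array([psnr(c, n) for c, n in zip(stims, noisy)])
        else:
            opt = optimize_threshold(stims, level, bank, t_grid=t_grid, mode=mode,
                                     seed=seed, noisy_images=noisy)
            vals = np.asarray(opt.per_image_psnr)
            tstars.append(opt.t_star)
        means.append(float(vals.mean()))
        sds.append(float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)

    condition = "noisy" if bank is None else "denoised"
    if fit_range_db is None:
        fit_range_db = (min(levels), max(levels)) if bank is None else (9.0, 27.0)
    lo, hi = fit_range_db
    x = np.array(levels)
    y = np.array(means)
    in_range = (x >= lo - 1e-9) & (x <= hi + 1e-9)
    if in_range.sum() < 2:
        raise ValueError(f"fit range {fit_range_db} covers fewer than 2 levels")
    slope_raw, _ = np.polyfit(x[in_range], y[in_range], 1)
    return PsnrCurve(
        noise_levels_db=tuple(levels), mean_psnr_db=tuple(means),
        sd_psnr_db=tuple(sds), n_images=len(stims), condition=condition,
        slope=float(slope_raw) / 2.0, slope_raw=float(slope_raw),
        fit_range_db=(float(lo), float(hi)), thresholds=tuple(tstars),
    )


def threshold_to_psnr(curve: PsnrCurve, threshold_db: float) -> float:
    """Project a detection threshold (noise contrast, dB) onto the PSNR axis
    by linear interpolation of the curve."""
    levels = np.asarray(curve.noise_levels_db)
    if not (levels.min() <= threshold_db <= levels.max()):
        raise ValueError(
            f"threshold {threshold_db} dB outside the curve range "
            f"[{levels.min()}, {levels.max()}]"
        )
    order = np.argsort(levels)
    return float(np.interp(threshold_db, levels[order],
                           np.asarray(curve.mean_psnr_db)[order]))
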