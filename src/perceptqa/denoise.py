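"""Multiscale log-Gabor denoising: decompose, threshold, reconstruct.

The bank holds single-lobe ("analytic") copies of the oriented log-Gabor
spectra, so each coefficient plane is complex: its magnitude is a local
contrast envelope and its phase the local phase.  Thresholding acts on
magnitudes with phases preserved.  Reconstruction multiplies each (possibly
thresholded) coefficient spectrum by its filter once more, Hermitian-
symmetrises the sum and divides by the pointwise sum of squared amplitudes —
a self-inverting normalised frame, exact to machine precision for the
un-thresholded path.

Coverage: oriented filters alone cannot tile the corners of the Fourier plane
(beyond the Nyquist circle) when orientation bandwidths are narrow, so the
bank includes an isotropic raised-cosine highpass "corner cap" as an ordinary
thresholdable element, and a protected raised-cosine lowpass residual below
the coarsest scale.  The finest scale defaults to Nyquist/sqrt(2) so the six
octave-spaced scales span the full spectrum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .config import derive_seed
from .filters import (
    FilterSpec,
    FourierGrid,
    _cartesian_value,
    _polar_value,
    build_fourier_grid,
    orientation_halfwidth,
)
from .stimuli import ImageStim, NoiseCondition, add_white_noise, noise_std_from_db

__all__ = [
    "FilterBankConfig",
    "FilterBank",
    "Decomposition",
    "ThresholdPolicy",
    "ThresholdOptResult",
    "build_bank",
    "decompose",
    "threshold_coeffs",
    "reconstruct",
    "denoise",
    "optimize_threshold",
]

log = logging.getLogger("perceptqa.denoise")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterBankConfig:
    """Parameters of a scales × orientations log-Gabor bank.

    ``orient_fwhh`` is the orientation bandwidth in degrees, full width at
    half height by default (``width_convention="fwhh"``); the number of
    orientations per scale is ``round(180 / orient_fwhh)``.  ``base_f0`` is
    the centre frequency of the finest scale in cycles/image and defaults to
    Nyquist/sqrt(2) so the bank reaches the corners of the spectrum.
    """

    size: int = 256
    n_scales: int = 6
    scale_spacing: float = 1.0  # octaves
    omega: float = 1.43
    orient_fwhh: float = 22.5
    family: str = "cartesian"
    base_f0: float | None = None
    width_convention: str = "fwhh"
    include_cap: bool = True
    include_highpass_residual: bool = False

    @property
    def n_orientations(self) -> int:
        n = round(180.0 / self.orient_fwhh)
        if abs(n * self.orient_fwhh - 180.0) > 1e-6 * 180.0:
            log.warning("orient_fwhh %.4g does not divide 180 evenly; using %d orientations",
                        self.orient_fwhh, n)
        return n

    @property
    def finest_f0(self) -> float:
        return self.base_f0 if self.base_f0 is not None else self.size / (2.0 * math.sqrt(2.0))

    @property
    def scale_f0s(self) -> tuple[float, ...]:
        return tuple(self.finest_f0 / 2.0 ** (s * self.scale_spacing)
                     for s in range(self.n_scales))

    @property
    def h(self) -> float:
        """Orientation half-width at half height, degrees."""
        return orientation_halfwidth(self.orient_fwhh, self.width_convention)


# ---------------------------------------------------------------------------
# Bank
# ---------------------------------------------------------------------------

class FilterBank:
    """A frame of single-lobe log-Gabor spectra plus residual bands.

    Attributes
    ----------
    elements:
        List of masked amplitude arrays in unshifted FFT layout; the first
        ``n_scales * n_orientations`` are the oriented filters (scale-major),
        optionally followed by the isotropic corner cap.
    lowpass, highpass:
        Protected residual spectra (highpass is ``None`` unless configured).
    noise_gain:
        Per-element RMS coefficient magnitude under unit-variance white pixel
        noise; used by noise-scaled threshold policies.
    """

    def __init__(self, config: FilterBankConfig, grid: FourierGrid | None = None):
        if grid is None:
            grid = build_fourier_grid(config.size)
        if grid.size != config.size:
            raise ValueError(
                f"grid size {grid.size} does not match bank config size {config.size}"
            )
        nyq = grid.nyquist
        if config.finest_f0 >= nyq:
            raise ValueError(
                f"finest centre frequency {config.finest_f0:.4g} must lie below "
                f"Nyquist ({nyq:.4g} cycles/image)"
            )
        self.config = config
        self.grid = grid
        size = config.size
        neg_idx = (-np.arange(size)) % size
        self._neg = np.ix_(neg_idx, neg_idx)

        h = config.h
        theta0s = [j * 180.0 / config.n_orientations
                   for j in range(config.n_orientations)]
        self.specs: list[FilterSpec] = []
        self.elements: list[np.ndarray] = []
        self.element_labels: list[tuple] = []
        f_sh = np.fft.ifftshift(grid.f)
        th_sh = np.fft.ifftshift(grid.theta)
        for s, f0 in enumerate(config.scale_f0s):
            for j, theta0 in enumerate(theta0s):
                spec = FilterSpec(f0=f0, theta0=theta0, omega=config.omega,
                                  h=h, family=config.family)
                if config.family == "cartesian":
                    amp = _cartesian_value(f_sh, th_sh, f0,
                                           math.radians(theta0), spec.sigma, spec.eta)
                else:
                    amp = _polar_value(f_sh, th_sh, f0, math.radians(theta0),
                                       config.omega, math.radians(h))
                amp[f_sh == 0] = 0.0
                # single positive lobe; the Nyquist row/col maps to itself
                # under frequency negation, so the mask is defined pairwise
                uft = f_sh * np.cos(th_sh - math.radians(theta0))
                keep = uft >= uft[self._neg]
                self.elements.append(np.where(keep, amp, 0.0))
                self.specs.append(spec)
                self.element_labels.append((s, j))

        with np.errstate(divide="ignore"):
            logf = np.log2(np.where(f_sh > 0, f_sh, np.finfo(float).tiny))
        if config.include_cap and not config.include_highpass_residual:
            t = np.clip((logf - math.log2(config.finest_f0)) / 0.5, 0.0, 1.0)
            cap = 0.5 - 0.5 * np.cos(np.pi * t)
            self.elements.append(cap)
            self.element_labels.append(("cap",))

        fmin = min(config.scale_f0s)
        t = np.clip(math.log2(fmin) - logf, 0.0, 1.0)
        self.lowpass = 0.5 - 0.5 * np.cos(np.pi * t)
        self.lowpass[f_sh == 0] = 1.0

        self.highpass = None
        if config.include_highpass_residual:
            t = np.clip((logf - math.log2(config.finest_f0)) / 0.5, 0.0, 1.0)
            self.highpass = 0.5 - 0.5 * np.cos(np.pi * t)

        D = np.zeros((size, size))
        for m in self.elements:
            D += m * m
        D = D + D[self._neg] + self.lowpass**2
        if self.highpass is not None:
            D = D + self.highpass**2
        if float(D[1:, :].min()) <= 1e-6 or float(D[0, 1:].min()) <= 1e-6:
            raise ValueError(
                "filter bank does not cover the spectrum: squared-amplitude sum "
                f"falls to {min(float(D[1:, :].min()), float(D[0, 1:].min())):.3g}; "
                "enable the corner cap or widen the bandwidths"
            )
        self._D = D
        # per-element complex-coefficient RMS under unit-variance white noise
        self.noise_gain = np.array([math.sqrt(float(np.mean(m * m)))
                                    for m in self.elements])

    # -- geometry ----------------------------------------------------------
    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_oriented(self) -> int:
        return self.config.n_scales * self.config.n_orientations

    def element_scale(self, index: int) -> int | None:
        """Scale index of an element (None for the corner cap)."""
        label = self.element_labels[index]
        return label[0] if label[0] != "cap" else None

    def _key(self) -> tuple:
        return (self.config, self.grid.size)

    # -- transforms --------------------------------------------------------
    def decompose(self, image: np.ndarray | ImageStim) -> "Decomposition":
        pixels = image.pixels if isinstance(image, ImageStim) else np.asarray(image, float)
        if pixels.shape != (self.grid.size, self.grid.size):
            raise ValueError(
                f"image shape {pixels.shape} does not match bank grid "
                f"({self.grid.size}x{self.grid.size})"
            )
        X = np.fft.fft2(pixels)
        coeffs = [np.fft.ifft2(m * X) for m in self.elements]
        lowpass = np.fft.ifft2(self.lowpass * X).real
        highpass = (np.fft.ifft2(self.highpass * X).real
                    if self.highpass is not None else None)
        return Decomposition(coeffs=coeffs, lowpass=lowpass,
                             highpass=highpass, bank_key=self._key())

    def reconstruct(self, decomp: "Decomposition") -> np.ndarray:
        if decomp.bank_key != self._key():
            raise ValueError("decomposition was produced by a different bank")
        size = self.grid.size
        Y = np.zeros((size, size), dtype=complex)
        for m, c in zip(self.elements, decomp.coeffs):
            Y += m * np.fft.fft2(c)
        Y = Y + np.conj(Y[self._neg])
        Y += self.lowpass * np.fft.fft2(decomp.lowpass)
        if self.highpass is not None:
            Y += self.highpass * np.fft.fft2(decomp.highpass)
        return np.fft.ifft2(Y / self._D).real


def build_bank(config: FilterBankConfig, grid: FourierGrid | None = None) -> FilterBank:
    """Construct a :class:`FilterBank` (functional alias for the constructor)."""
    return FilterBank(config, grid)


# ---------------------------------------------------------------------------
# Decomposition & thresholding
# ---------------------------------------------------------------------------

@dataclass
class Decomposition:
    """Complex coefficient planes plus protected residual bands."""

    coeffs: list[np.ndarray] = field(repr=False)
    lowpass: np.ndarray = field(repr=False)
    highpass: np.ndarray | None = field(repr=False, default=None)
    bank_key: tuple = ()


@dataclass(frozen=True)
class ThresholdPolicy:
    """Coefficient-magnitude thresholding rule.

    ``T`` is an amplitude in coefficient-magnitude units: a scalar broadcast
    over all elements, or a per-element sequence.  With
    ``relative_to_noise=True`` the effective per-element threshold becomes
    ``T * noise_std * bank.noise_gain[j]`` — i.e. ``T`` counts per-subband
    noise standard deviations, the subband-adaptive rule used by log-Gabor
    denoisers.  ``scales`` restricts thresholding to the listed scale indices
    (0 = finest); the corner cap is treated as part of the finest scale.
    Residual bands are never thresholded.
    """

    T: float | tuple = 0.0
    mode: str = "hard"
    scales: tuple | None = None
    relative_to_noise: bool = False
    noise_std: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("hard", "soft"):
            raise ValueError(f"mode must be 'hard' or 'soft', got {self.mode!r}")
        t = np.atleast_1d(np.asarray(self.T, dtype=float))
        if np.any(t < 0):
            raise ValueError("thresholds must be non-negative")
        if self.relative_to_noise and self.noise_std is None:
            raise ValueError("relative_to_noise policies need noise_std")

    @classmethod
    def noise_scaled(cls, t: float, noise_db: float, mode: str = "hard",
                     scales: tuple | None = None) -> "ThresholdPolicy":
        """Threshold ``t`` in units of per-subband noise RMS at ``noise_db``."""
        return cls(T=t, mode=mode, scales=scales, relative_to_noise=True,
                   noise_std=noise_std_from_db(noise_db))

    def per_element(self, bank: FilterBank) -> np.ndarray:
        t = np.asarray(self.T, dtype=float)
        if t.ndim == 0:
            t = np.full(bank.n_elements, float(t))
        elif t.size == bank.config.n_scales:
            # per-scale values broadcast over orientations; cap follows finest
            full = np.empty(bank.n_elements)
            for j in range(bank.n_elements):
                s = bank.element_scale(j)
                full[j] = t[0 if s is None else s]
            t = full
        elif t.size != bank.n_elements:
            raise ValueError(
                f"threshold vector of length {t.size}; expected scalar, "
                f"{bank.config.n_scales} (per scale) or {bank.n_elements}"
            )
        if self.relative_to_noise:
            t = t * self.noise_std * bank.noise_gain
        if self.scales is not None:
            keep = np.ones(bank.n_elements, dtype=bool)
            for j in range(bank.n_elements):
                s = bank.element_scale(j)
                keep[j] = (0 if s is None else s) in self.scales
            t = np.where(keep, t, 0.0)
        return t


def decompose(image, bank: FilterBank) -> Decomposition:
    return bank.decompose(image)


def threshold_coeffs(decomp: Decomposition, policy: ThresholdPolicy,
                     bank: FilterBank) -> Decomposition:
    """Apply hard or soft magnitude thresholding; residuals untouched."""
    thresholds = policy.per_element(bank)
    out = []
    for c, T in zip(decomp.coeffs, thresholds):
        if T == 0:
            out.append(c)
            continue
        mag = np.abs(c)
        if policy.mode == "hard":
            out.append(np.where(mag < T, 0.0, c))
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                shrink = np.where(mag > 0, np.maximum(mag - T, 0.0) / np.where(mag > 0, mag, 1.0), 0.0)
            out.append(c * shrink)
    return Decomposition(coeffs=out, lowpass=decomp.lowpass,
                         highpass=decomp.highpass, bank_key=decomp.bank_key)


def reconstruct(decomp: Decomposition, bank: FilterBank) -> np.ndarray:
    return bank.reconstruct(decomp)


def denoise(image, bank: FilterBank, policy: ThresholdPolicy) -> np.ndarray:
    """decompose → threshold → reconstruct, clipped to the unit interval."""
    out = bank.reconstruct(threshold_coeffs(bank.decompose(image), policy, bank))
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Threshold optimisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdOptResult:
    t_star: float
    mean_psnr: float
    per_image_psnr: tuple
    t_grid: tuple
    grid_mean_psnr: tuple
    poly_coeffs: tuple
    fell_back: bool
    noise_db: float
    mode: str


DEFAULT_T_GRID = tuple(np.geomspace(0.7, 5.6, 9))


def optimize_threshold(images, noise_db: float, bank: FilterBank,
                       t_grid=None, mode: str = "hard", seed: int = 0,
                       degree: int = 4, fit_tol: float = 0.2,
                       noisy_images=None) -> ThresholdOptResult:
    """PSNR-optimal noise-scaled threshold for one noise level.

    Noise realisations are added internally with per-image seeds derived from
    ``seed`` (or supplied via ``noisy_images`` to share realisations with a
    caller).  A degree-``degree`` polynomial is fitted to mean PSNR as a
    function of log2(t) over a geometric grid of noise-relative thresholds and
    maximised on the grid's hull; if the fitted optimum measures worse than
    the best grid point by more than ``fit_tol`` dB, the best grid point is
    used instead (logged).
    """
    from .metrics import psnr

    t_grid = np.asarray(DEFAULT_T_GRID if t_grid is None else t_grid, dtype=float)
    if t_grid.size < 5:
        raise ValueError("threshold grid needs at least 5 points")
    clean = [im.pixels if isinstance(im, ImageStim) else np.asarray(im, float)
             for im in images]
    if noisy_images is None:
        noisy = [
            add_white_noise(
                im if isinstance(im, ImageStim) else ImageStim(pixels=np.asarray(im, float)),
                NoiseCondition(noise_db, derive_seed(seed, "optnoise", noise_db, i)),
            ).pixels
            for i, im in enumerate(images)
        ]
    else:
        noisy = [im.pixels if isinstance(im, ImageStim) else np.asarray(im, float)
                 for im in noisy_images]
    decs = [bank.decompose(n) for n in noisy]

    def measure(t: float) -> np.ndarray:
        policy = ThresholdPolicy.noise_scaled(t, noise_db, mode=mode)
        vals = []
        for d, c in zip(decs, clean):
            den = np.clip(bank.reconstruct(threshold_coeffs(d, policy, bank)), 0, 1)
            vals.append(psnr(c, den))
        return np.asarray(vals)

    grid_psnr = np.array([measure(t).mean() for t in t_grid])
    x = np.log2(t_grid)
    coeffs = np.polyfit(x, grid_psnr, deg=degree)
    dense = np.linspace(x[0], x[-1], 512)
    fitted = np.polyval(coeffs, dense)
    t_fit = float(2.0 ** dense[np.argmax(fitted)])

    per_image = measure(t_fit)
    mean_fit = float(per_image.mean())
    best_idx = int(np.argmax(grid_psnr))
    fell_back = mean_fit < grid_psnr[best_idx] - fit_tol
    if fell_back:
        log.warning("polynomial fit at %.1f dB not concave/competitive "
                    "(%.2f vs %.2f dB); falling back to best grid point",
                    noise_db, mean_fit, grid_psnr[best_idx])
        t_fit = float(t_grid[best_idx])
        per_image = measure(t_fit)
        mean_fit = float(per_image.mean())
    return ThresholdOptResult(
        t_star=t_fit, mean_psnr=mean_fit, per_image_psnr=tuple(per_image),
        t_grid=tuple(t_grid), grid_mean_psnr=tuple(grid_psnr),
        poly_coeffs=tuple(coeffs), fell_back=fell_back,
        noise_db=noise_db, mode=mode,
    )
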