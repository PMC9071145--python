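"""Log-Gabor filter construction in the Fourier domain.

Two filter families are provided:

* **Cartesian-separable** filters with polar parameters: the product of a
  Gaussian on a log spatial-frequency axis (evaluated along the filter's
  preferred orientation) and a Gaussian along the orthogonal Cartesian axis.
  The orthogonal scale ``eta`` is derived from the orientation half-width at
  half-height ``h`` so that the 2-D spectrum equals 0.5 at ``(f0, theta0 + h)``.
* **Polar-separable** filters: a log-frequency Gaussian times a Gaussian in
  angular difference, completed by 180° rotation so the spectrum carries both
  symmetric lobes.

Both families are zero at DC for any phase, which makes every spatial kernel
D.C.-balanced.  Angles are degrees at the interface and radians internally.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "FourierGrid",
    "FilterSpec",
    "FilterSpectrum",
    "FilterKernel",
    "build_fourier_grid",
    "eta_param",
    "max_orientation_bandwidth",
    "orientation_halfwidth",
    "cartesian_loggabor_value",
    "polar_loggabor_value",
    "cartesian_loggabor_spectrum",
    "polar_loggabor_spectrum",
    "spectrum_to_kernel",
    "write_spectrum",
    "write_kernel",
    "write_spec_text",
    "SIGMA_PER_FWHH",
]

#: Conversion between the standard deviation and the full width at half height
#: of a Gaussian, rounded to three decimals as is conventional in the
#: biological-vision literature (the exact value is 1/(2*sqrt(2*ln 2)) = 0.42466).
SIGMA_PER_FWHH = 0.424

_LN4 = math.log(4.0)


# ---------------------------------------------------------------------------
# Fourier grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FourierGrid:
    """Centred Fourier-domain coordinates for an even ``size`` × ``size`` grid.

    The DC component sits at 1-based index ``(size+2)/2`` on both axes
    (0-based ``size//2``).  ``u`` varies along columns (x), ``v`` along rows.
    Frequencies are in cycles/image.
    """

    size: int
    u: np.ndarray = field(repr=False)
    v: np.ndarray = field(repr=False)
    f: np.ndarray = field(repr=False)
    theta: np.ndarray = field(repr=False)

    @property
    def dc_index(self) -> int:
        """0-based row/column index of the DC component."""
        return self.size // 2

    @property
    def nyquist(self) -> float:
        return self.size / 2.0


def build_fourier_grid(size: int) -> FourierGrid:
    """Build the centred frequency/orientation coordinate grid.

    Parameters
    ----------
    size:
        Width and height in pixels; must be even and at least 8.
    """
    if size % 2 != 0 or size < 8:
        raise ValueError(
            f"grid size must be an even integer >= 8, got {size}"
        )
    coords = np.arange(1, size + 1, dtype=float) - (size + 2) / 2.0
    u, v = np.meshgrid(coords, coords)
    f = np.hypot(u, v)
    theta = np.arctan2(v, u)
    return FourierGrid(size=size, u=u, v=v, f=f, theta=theta)


# ---------------------------------------------------------------------------
# Filter specification
# ---------------------------------------------------------------------------

def orientation_halfwidth(value_deg: float, convention: str = "fwhh") -> float:
    """Convert an orientation bandwidth to the half-width at half-height ``h``.

    The experimental literature sometimes quotes orientation bandwidths as
    full widths (e.g. 11.25°–45°) while the filter equations use the
    half-width ``h``.  ``convention`` makes the choice explicit:
    ``"fwhh"`` halves the value, ``"hwhh"`` passes it through.
    """
    if convention == "fwhh":
        return value_deg / 2.0
    if convention == "hwhh":
        return float(value_deg)
    raise ValueError(f"unknown width convention {convention!r}")


def max_orientation_bandwidth(omega: float) -> float:
    """Largest admissible orientation half-width ``h`` (degrees) for a
    Cartesian-separable log-Gabor of spatial-frequency bandwidth ``omega``.

    Determined numerically (bisection) as the point where the orthogonal
    scale ``eta`` ceases to be defined, i.e. where
    ``ln 4 - (log2|cos h| / (0.424 omega))**2`` changes sign.  Over
    0.7 < omega < 5 the result tracks the straight line
    ``15*log2(omega) + 45`` to within about a degree.
    """
    if not (0.1 <= omega <= 8.0):
        raise ValueError(
            f"omega={omega} outside the supported range [0.1, 8] octaves"
        )
    s = SIGMA_PER_FWHH * omega

    def g(h_rad: float) -> float:
        return _LN4 - (math.log2(math.cos(h_rad)) / s) ** 2

    # g decreases from ln4 at h=0 to -inf as h -> 90 deg.
    h_rad = brentq(g, 1e-12, math.pi / 2 - 1e-12, xtol=1e-12)
    return math.degrees(h_rad)


@dataclass(frozen=True)
class FilterSpec:
    """Polar parameters of one log-Gabor element.

    Parameters
    ----------
    f0:
        Centre (peak) spatial frequency, cycles/image.
    theta0:
        Centre orientation, degrees.
    omega:
        Spatial-frequency bandwidth, full width at half height, octaves.
    h:
        Orientation bandwidth, degrees: the half-width at half-height at the
        best spatial frequency (see :func:`orientation_halfwidth`).
    phi:
        Phase angle, degrees.  0 gives the even-symmetric (cosine-phase)
        kernel, 90 the odd-symmetric one.
    family:
        ``"cartesian"`` or ``"polar"``.
    """

    f0: float
    theta0: float = 0.0
    omega: float = 1.43
    h: float = 22.5
    phi: float = 0.0
    family: str = "cartesian"

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError(f"f0 must be positive, got {self.f0}")
        if self.omega <= 0:
            raise ValueError(f"omega must be positive, got {self.omega}")
        if not (0 < self.h < 90):
            raise ValueError(f"h must lie in (0, 90) degrees, got {self.h}")
        if self.family not in ("cartesian", "polar"):
            raise ValueError(f"unknown filter family {self.family!r}")
        if self.family == "cartesian":
            # raises if h is at or above the bandwidth limit
            eta_param(self.f0, self.omega, self.h)

    @property
    def sigma(self) -> float:
        """Log-frequency Gaussian standard deviation, octaves (= 0.424*omega)."""
        return SIGMA_PER_FWHH * self.omega

    @property
    def eta(self) -> float:
        """Orthogonal-Gaussian scale, cycles/image (Cartesian family only)."""
        if self.family != "cartesian":
            raise AttributeError("eta is defined for the cartesian family only")
        return eta_param(self.f0, self.omega, self.h)


def eta_param(f0: float, omega: float, h: float) -> float:
    """Orthogonal-Gaussian scale ``eta`` for a Cartesian-separable log-Gabor.

    ``eta = f0 sin(h) sqrt(1 / (ln 4 - (log2|cos h| / (0.424 omega))**2))``,
    chosen so that the 2-D spectrum equals 0.5 at ``(f0, theta0 + h)``.

    Raises
    ------
    ValueError
        If ``h`` is at or above the orientation-bandwidth limit for this
        ``omega`` (the expression under the root is non-positive).
    """
    if f0 <= 0 or omega <= 0:
        raise ValueError("f0 and omega must be positive")
    h_rad = math.radians(h)
    k = (math.log2(abs(math.cos(h_rad))) / (SIGMA_PER_FWHH * omega)) ** 2
    root_arg = _LN4 - k
    if root_arg <= 0:
        raise ValueError(
            f"h={h} deg is at or above the orientation-bandwidth limit "
            f"({max_orientation_bandwidth(omega):.2f} deg for omega={omega})"
        )
    return f0 * math.sin(h_rad) * math.sqrt(1.0 / root_arg)


# ---------------------------------------------------------------------------
# Continuous-coordinate evaluation
# ---------------------------------------------------------------------------

def _cartesian_value(f, theta, f0, theta0_rad, sigma, eta):
    """Cartesian-separable amplitude at continuous polar coordinates."""
    f = np.asarray(f, dtype=float)
    theta = np.asarray(theta, dtype=float)
    fc = f * np.abs(np.cos(theta - theta0_rad))
    with np.errstate(divide="ignore", invalid="ignore"):
        radial = np.exp(-(np.log2(fc / f0)) ** 2 / (2.0 * sigma**2))
    # fc == 0 (DC, or orientation exactly orthogonal): amplitude -> 0 in the limit
    radial = np.where(fc > 0, radial, 0.0)
    orth = np.exp(-((f * np.sin(theta - theta0_rad)) ** 2) / (2.0 * eta**2))
    return radial * orth


def _polar_value(f, theta, f0, theta0_rad, omega, h_rad):
    """Polar-separable amplitude (both lobes) at continuous coordinates.

    The radial term follows the natural-log parameterisation with scale
    ``ln(omega)``; the angular term is Gaussian in the wrapped angular
    difference with scale ``h`` (radians), completed by its 180°-rotated lobe.
    """
    f = np.asarray(f, dtype=float)
    theta = np.asarray(theta, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        radial = np.exp(-(np.log(f / f0)) ** 2 / (2.0 * math.log(omega) ** 2))
    radial = np.where(f > 0, radial, 0.0)

    def lobe(t0):
        d = np.abs(np.arctan2(np.sin(theta - t0), np.cos(theta - t0)))
        return np.exp(-(d**2) / (2.0 * h_rad**2))

    return radial * (lobe(theta0_rad) + lobe(theta0_rad + math.pi))


def cartesian_loggabor_value(f, theta_deg, spec: FilterSpec):
    """Evaluate the Cartesian-separable spectrum at continuous ``(f, theta)``.

    This is the defining formula, free of grid quantisation; use it for
    half-height checks at exact coordinates.
    """
    if spec.family != "cartesian":
        raise ValueError("spec.family must be 'cartesian'")
    return _cartesian_value(
        f, np.radians(theta_deg), spec.f0, math.radians(spec.theta0),
        spec.sigma, spec.eta,
    )


def polar_loggabor_value(f, theta_deg, spec: FilterSpec):
    """Evaluate the polar-separable spectrum (both lobes) at ``(f, theta)``."""
    if spec.family != "polar":
        raise ValueError("spec.family must be 'polar'")
    return _polar_value(
        f, np.radians(theta_deg), spec.f0, math.radians(spec.theta0),
        spec.omega, math.radians(spec.h),
    )


# ---------------------------------------------------------------------------
# Grid-sampled spectra and kernels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterSpectrum:
    """A filter's non-negative Fourier amplitude sampled on a grid.

    ``amplitude`` is laid out like the grid (DC at the centre), peaks at 1
    near ``(f0, theta0)``, is exactly 0 at DC and 180°-rotation symmetric.
    """

    amplitude: np.ndarray = field(repr=False)
    grid: FourierGrid
    spec: FilterSpec


@dataclass(frozen=True)
class FilterKernel:
    """Real space-domain kernel, peak-normalised to max |value| = 1."""

    values: np.ndarray = field(repr=False)
    phase: float
    spec: FilterSpec


def cartesian_loggabor_spectrum(grid: FourierGrid, spec: FilterSpec) -> FilterSpectrum:
    """Sample a Cartesian-separable log-Gabor amplitude spectrum on ``grid``."""
    if spec.family != "cartesian":
        raise ValueError("spec.family must be 'cartesian'")
    amp = _cartesian_value(
        grid.f, grid.theta, spec.f0, math.radians(spec.theta0),
        spec.sigma, spec.eta,
    )
    amp[grid.f == 0] = 0.0
    return FilterSpectrum(amplitude=amp, grid=grid, spec=spec)


def polar_loggabor_spectrum(grid: FourierGrid, spec: FilterSpec) -> FilterSpectrum:
    """Sample a polar-separable log-Gabor amplitude spectrum on ``grid``.

    Both symmetric lobes are included (180° rotational completion).
    """
    if spec.family != "polar":
        raise ValueError("spec.family must be 'polar'")
    amp = _polar_value(
        grid.f, grid.theta, spec.f0, math.radians(spec.theta0),
        spec.omega, math.radians(spec.h),
    )
    amp[grid.f == 0] = 0.0
    return FilterSpectrum(amplitude=amp, grid=grid, spec=spec)


def spectrum_to_kernel(spectrum: FilterSpectrum, phi: float | None = None) -> FilterKernel:
    """Inverse-transform an amplitude spectrum into a spatial kernel.

    The requested phase is written directly into the phase spectrum before the
    inverse transform: the half-plane on the filter's positive frequency axis
    receives ``exp(-i*phi)`` and the opposite half its conjugate, so ``phi=0``
    yields the even-symmetric (cosine-phase) kernel and ``phi=90`` the
    odd-symmetric one.  The kernel is peak-normalised; its pixel sum is ~0
    because the amplitude at DC is zero.
    """
    grid = spectrum.grid
    spec = spectrum.spec
    if phi is None:
        phi = spec.phi
    phi_rad = math.radians(phi)
    uft = grid.f * np.cos(grid.theta - math.radians(spec.theta0))
    amp = spectrum.amplitude
    cx = np.zeros(amp.shape, dtype=complex)
    cx[uft > 0] = amp[uft > 0] * complex(math.cos(phi_rad), -math.sin(phi_rad))
    cx[uft < 0] = amp[uft < 0] * complex(math.cos(phi_rad), math.sin(phi_rad))
    # uft == 0: self-mirroring line; the real (cosine) component keeps the
    # spectrum Hermitian there.  Amplitudes on this line are ~0 anyway.
    on_axis = uft == 0
    cx[on_axis] = amp[on_axis] * math.cos(phi_rad)
    img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(cx)))
    resid = np.abs(img.imag).max()
    real = img.real
    peak = np.abs(real).max()
    if peak == 0:
        raise ValueError("spectrum is identically zero; no kernel")
    # The Nyquist row/column of an even grid aliases +/- Nyquist, so the
    # sampled spectrum is not perfectly Hermitian there; the filter amplitude
    # on those lines is vanishingly small, leaving a tiny residue.
    if resid > 1e-4 * peak:
        raise ValueError(f"kernel has non-negligible imaginary residue {resid:g}")
    return FilterKernel(values=real / peak, phase=float(phi), spec=spec)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_kernel(kernel: FilterKernel, path) -> None:
    """Write a kernel as 32-bit float TIFF or peak-mapped 16-bit PNG."""
    _write_image(kernel.values, path)


def write_spectrum(spectrum: FilterSpectrum, path) -> None:
    """Write an amplitude spectrum as 32-bit float TIFF or 16-bit PNG."""
    _write_image(spectrum.amplitude, path)


def _write_image(arr: np.ndarray, path) -> None:
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, arr.astype(np.float32))
    elif path.lower().endswith(".png"):
        from PIL import Image

        lo, hi = float(arr.min()), float(arr.max())
        scale = (hi - lo) or 1.0
        mapped = np.round((arr - lo) / scale * 65535).astype(np.uint16)
        Image.fromarray(mapped).save(path)
    else:
        raise ValueError(f"unsupported image format for {path!r} (use .tiff or .png)")


def write_spec_text(spec: FilterSpec, path) -> None:
    """Serialise a FilterSpec as ``key: value`` lines."""
    lines = [f"{k}: {v}" for k, v in dataclasses.asdict(spec).items()]
    if spec.family == "cartesian":
        lines.append(f"eta: {spec.eta}")
    lines.append(f"sigma: {spec.sigma}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
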