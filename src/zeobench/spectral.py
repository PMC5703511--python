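"""Spectral data model: wavelength axes, spectra, cubes, virtual filters.

All spectral arithmetic in the package goes through this module. The central
operation is band integration — emulating a commercial bandpass emission
filter by integrating a per-pixel emission spectrum over the filter's
transmission window — which is how filter-based microscopy channels are
reconstructed from hyperspectral raster scans.

Conventions
-----------
* Wavelengths are in nm on a strictly increasing grid; the default grid is
  400–820 nm at 1 nm.
* Intensities are arbitrary units (a.u.); no detector-efficiency correction
  is applied anywhere.
* Images and cubes are indexed ``[y, x]`` / ``[y, x, wavelength]`` with
  0-based indices, (0, 0) the top-left pixel, x rightward, y downward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

DEFAULT_WAVELENGTH_RANGE = (400.0, 820.0)
DEFAULT_WAVELENGTH_STEP = 1.0


@dataclass(frozen=True)
class WavelengthAxis:
    """Strictly increasing wavelength grid in nm."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("axis needs at least 2 wavelength samples")
        if not np.all(np.diff(v) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @classmethod
    def default(cls) -> "WavelengthAxis":
        lo, hi = DEFAULT_WAVELENGTH_RANGE
        n = int(round((hi - lo) / DEFAULT_WAVELENGTH_STEP)) + 1
        return cls(np.linspace(lo, hi, n))

    @property
    def step(self) -> float:
        """Nominal grid spacing (median of the sample spacings)."""
        return float(np.median(np.diff(self.values)))

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return isinstance(other, WavelengthAxis) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self) -> int:
        return hash(self.values.tobytes())


@dataclass
class EmissionSpectrum:
    """Intensity vs wavelength; the unit of all spectral math.

    Raw spectra are nonnegative. Background-subtracted derived spectra may
    dip below zero and carry ``background_subtracted=True``.
    """

    axis: WavelengthAxis
    intensity: np.ndarray
    background_subtracted: bool = False

    def __post_init__(self) -> None:
        y = np.asarray(self.intensity, dtype=float)
        if y.shape != (len(self.axis),):
            raise ValueError(
                f"intensity length {y.size} != axis length {len(self.axis)}"
            )
        if not self.background_subtracted and np.any(y < 0):
            raise ValueError("raw spectrum intensities must be >= 0")
        self.intensity = y

    def total(self) -> float:
        """Full-range trapezoidal integral (a.u.·nm)."""
        return float(np.trapezoid(self.intensity, self.axis.values))


@dataclass(frozen=True)
class FilterChannel:
    """Ideal top-hat emission window emulating a bandpass filter."""

    name: str
    lo_nm: float
    hi_nm: float
    transmission: float = 1.0

    def __post_init__(self) -> None:
        if not self.lo_nm < self.hi_nm:
            raise ValueError("filter window requires lo_nm < hi_nm")
        if not 0 < self.transmission <= 1:
            raise ValueError("transmission must be in (0, 1]")


@dataclass
class SpectralCube:
    """One raster scan at one excitation setting: data[y, x, wavelength]."""

    data: np.ndarray
    axis: WavelengthAxis
    pixel_size_um: float = 0.5
    excitation_nm: float = float("nan")
    excitation_power_uW: float = float("nan")
    integration_time_s: float = 1.0

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3:
            raise ValueError("cube data must be 3-D (ny, nx, n_wavelength)")
        if d.shape[2] != len(self.axis):
            raise ValueError(
                f"cube has {d.shape[2]} wavelength frames but axis has "
                f"{len(self.axis)} samples"
            )
        if d.shape[0] < 1 or d.shape[1] < 1:
            raise ValueError("cube needs at least one pixel")
        self.data = d

    @property
    def ny(self) -> int:
        return self.data.shape[0]

    @property
    def nx(self) -> int:
        return self.data.shape[1]


def band_weights(axis: WavelengthAxis, lo_nm: float, hi_nm: float) -> np.ndarray:
    """Quadrature weights w such that w·f is the trapezoidal integral of the
    piecewise-linear interpolant of f over [lo_nm, hi_nm] ∩ axis range.

    Window endpoints inside a grid segment are handled by linear
    interpolation of the integrand, so integrals are exactly additive over
    adjacent windows sharing an endpoint.
    """
    x = axis.values
    w = np.zeros_like(x)
    lo = max(lo_nm, x[0])
    hi = min(hi_nm, x[-1])
    if hi <= lo:
        warnings.warn(
            f"filter window [{lo_nm}, {hi_nm}] nm does not overlap the "
            f"axis range [{x[0]}, {x[-1]}] nm; integral is 0",
            stacklevel=2,
        )
        return w
    x0, x1 = x[:-1], x[1:]
    a = np.maximum(x0, lo)
    b = np.minimum(x1, hi)
    seg = b > a
    a, b = a[seg], b[seg]
    h = (x1 - x0)[seg]
    half = 0.5 * (b - a)
    # f(a) and f(b) are linear in the segment's node values
    idx = np.nonzero(seg)[0]
    np.add.at(w, idx, half * ((x1[seg] - a) + (x1[seg] - b)) / h)
    np.add.at(w, idx + 1, half * ((a - x0[seg]) + (b - x0[seg])) / h)
    return w


def integrate_band(spectrum: EmissionSpectrum, channel: FilterChannel) -> float:
    """Transmission × trapezoidal integral of the spectrum over the filter
    window (a.u.·nm). Empty overlap yields 0 with a warning."""
    w = band_weights(spectrum.axis, channel.lo_nm, channel.hi_nm)
    return float(channel.transmission * (w @ spectrum.intensity))


def extract_channel_image(cube: SpectralCube, channel: FilterChannel) -> np.ndarray:
    """Per-pixel band integration: the image seen through the filter."""
    w = band_weights(cube.axis, channel.lo_nm, channel.hi_nm)
    return channel.transmission * (cube.data @ w)


@dataclass
class CalibrationFit:
    """Polynomial mapping detector pixel index -> wavelength in nm."""

    coefficients: np.ndarray  # ascending powers
    residuals: np.ndarray  # reference − fitted, per reference line

    @property
    def max_residual(self) -> float:
        return float(np.max(np.abs(self.residuals)))

    def apply(self, positions) -> np.ndarray:
        return np.polynomial.polynomial.polyval(
            np.asarray(positions, dtype=float), self.coefficients
        )


def calibrate_wavelength(
    peak_pixel_positions, reference_lines_nm, degree: int = 1
) -> CalibrationFit:
    """Least-squares polynomial wavelength calibration against reference
    emission lines (e.g. of a neon lamp)."""
    pos = np.asarray(peak_pixel_positions, dtype=float)
    ref = np.asarray(reference_lines_nm, dtype=float)
    if pos.shape != ref.shape:
        raise ValueError("positions and reference lines must have equal length")
    if pos.size < degree + 1:
        raise ValueError(
            f"underdetermined fit: {pos.size} lines for degree {degree} "
            f"(need >= {degree + 1})"
        )
    coeffs = np.polynomial.polynomial.polyfit(pos, ref, degree)
    residuals = ref - np.polynomial.polynomial.polyval(pos, coeffs)
    return CalibrationFit(coefficients=coeffs, residuals=residuals)


def diagonal_profile(image: np.ndarray) -> np.ndarray:
    """Pixel intensities along the main diagonal of a square image,
    top-left corner to bottom-right corner."""
    img = np.asarray(image)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError(f"diagonal profile requires a square image, got {img.shape}")
    n = img.shape[0]
    return img[np.arange(n), np.arange(n)].copy()
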