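"""Emission and excitation line-shape models.

Two families cover the emitters in the zeolite/PVA model system:

* :class:`AsymmetricPeakShape` — a broad, red-tailed band for organic dyes,
  parameterised by its mode, FWHM and an asymmetry factor (the log-normal
  peak function of Siano & Metzler, the standard empirical description of
  dye emission bands).
* :class:`LineSetShape` — a sum of narrow Gaussian lines for the f-f
  transitions of trivalent lanthanide ions (Eu3+, Tb3+), whose sharp peaks
  are what makes zeolite pixels spectrally identifiable against the broad
  dye background.

``density`` is peak-normalised (max == 1) and is used for extinction-shape
interpolation; ``sample`` returns a unit-area discretisation on a wavelength
axis and is used as an emission spectral density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

_4LN2 = 4.0 * math.log(2.0)


@dataclass(frozen=True)
class AsymmetricPeakShape:
    """Log-normal peak: mode at ``peak_nm``, full width ``fwhm_nm``.

    ``asymmetry`` (rho) is the ratio of the red-side to the blue-side
    half-width; rho > 1 gives the usual red tail of dye emission, rho < 1
    a blue tail (useful for excitation bands), rho == 1 degenerates to a
    Gaussian.
    """

    peak_nm: float
    fwhm_nm: float
    asymmetry: float = 1.4

    kind = "broad_dye"

    def __post_init__(self) -> None:
        if self.peak_nm <= 0 or self.fwhm_nm <= 0 or self.asymmetry <= 0:
            raise ValueError("peak_nm, fwhm_nm and asymmetry must be positive")

    def density(self, wavelength_nm) -> np.ndarray:
        wl = np.asarray(wavelength_nm, dtype=float)
        rho = self.asymmetry
        if abs(rho - 1.0) < 1e-9:
            return np.exp(-_4LN2 * (wl - self.peak_nm) ** 2 / self.fwhm_nm**2)
        arg = 1.0 + (wl - self.peak_nm) * (rho**2 - 1.0) / (rho * self.fwhm_nm)
        out = np.zeros_like(arg)
        ok = arg > 0
        alpha = math.log(2.0) / math.log(rho) ** 2
        out[ok] = np.exp(-alpha * np.log(arg[ok]) ** 2)
        return out

    def sample(self, axis_values: np.ndarray) -> np.ndarray:
        """Unit-area density on the given wavelength grid (trapezoid norm)."""
        d = self.density(axis_values)
        area = np.trapezoid(d, axis_values)
        if area <= 0:
            raise ValueError("shape has no support on the given axis")
        return d / area


@dataclass(frozen=True)
class LineSetShape:
    """Sum of Gaussian lines ``(center_nm, fwhm_nm, relative_intensity)``."""

    lines: tuple = field(default_factory=tuple)

    kind = "lanthanide_lines"

    def __post_init__(self) -> None:
        lines = tuple(tuple(map(float, ln)) for ln in self.lines)
        if not lines:
            raise ValueError("at least one line required")
        for c, f, r in lines:
            if c <= 0 or f <= 0 or r < 0:
                raise ValueError("line parameters must be positive")
        object.__setattr__(self, "lines", lines)

    @property
    def dominant_line_nm(self) -> float:
        return max(self.lines, key=lambda ln: ln[2])[0]

    def density(self, wavelength_nm) -> np.ndarray:
        wl = np.asarray(wavelength_nm, dtype=float)
        out = np.zeros_like(wl, dtype=float)
        for c, f, r in self.lines:
            out += r * np.exp(-_4LN2 * (wl - c) ** 2 / f**2)
        peak = max(r for _, _, r in self.lines)
        return out / peak

    def sample(self, axis_values: np.ndarray) -> np.ndarray:
        d = self.density(axis_values)
        area = np.trapezoid(d, axis_values)
        if area <= 0:
            raise ValueError("shape has no support on the given axis")
        return d / area


# Default emission shapes. Dye peaks are the packaged emission maxima; widths
# and asymmetry are chosen to mimic typical fluorescein / rhodamine /
# carborhodamine emission bands. Lanthanide line positions are the standard
# Eu3+ 5D0->7FJ and Tb3+ 5D4->7FJ transition wavelengths with the dominant
# line at the packaged emission maximum; FWHM 8 nm keeps them "uniquely
# narrow" relative to the dyes.
DEFAULT_EMISSION_SHAPES = {
    "F18": AsymmetricPeakShape(517.0, 35.0, 1.4),
    "MitoTracker Red": AsymmetricPeakShape(598.0, 45.0, 1.4),
    "ATTO647N": AsymmetricPeakShape(664.0, 50.0, 1.4),
    "Eu": LineSetShape(((592.0, 8.0, 0.30), (616.0, 8.0, 1.00),
                        (650.0, 8.0, 0.20), (700.0, 8.0, 0.15))),
    "Tb": LineSetShape(((490.0, 8.0, 0.55), (544.0, 8.0, 1.00),
                        (585.0, 8.0, 0.25), (620.0, 8.0, 0.15))),
}

# Excitation shapes, peak-normalised, used only to interpolate epsilon away
# from the four tabulated laser lines. Dyes get a broad band around their
# absorption maximum; the lanthanide shapes are narrow f-f absorption lines
# whose relative heights reproduce the packaged laser-line epsilons.
DEFAULT_EXCITATION_SHAPES = {
    "F18": AsymmetricPeakShape(500.0, 60.0, 1 / 1.4),
    "MitoTracker Red": AsymmetricPeakShape(578.0, 70.0, 1 / 1.4),
    "ATTO647N": AsymmetricPeakShape(646.0, 60.0, 1 / 1.4),
    "Eu": LineSetShape(((394.0, 5.0, 1.0), (465.0, 5.0, 0.132))),
    "Tb": LineSetShape(((378.0, 8.0, 1.0), (488.0, 8.0, 2.2e-4))),
}
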