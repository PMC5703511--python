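"""Synthetic model-system generator.

Emulates the benchmark sample: a homogeneous dye-stained PVA film carrying
micron-scale lanthanide-doped LTA zeolite particles, imaged by a raster-
scanning confocal microscope that records a full emission spectrum per
pixel. The default geometry is a 10 × 10 pixel scan of a 5 × 5 um area at
1 s integration per pixel; four excitation wavelengths are used in four
separate quadrants around one zeolite whose centre sits at a corner of each
image, which minimises bleaching of the shared region.

Forward model per pixel (expected counts per wavelength sample)::

    I(lambda) = background
              + sum_species k * c * eps(lambda_exc) * QY * P * t
                            * bleach(elapsed) * shape(lambda)

with ``k`` a global scale constant mapping the arbitrary photophysical
units to pseudo-counts, ``c`` the stain concentration (or the zeolite's
effective dopant loading weighted by an annular bright-rim profile), ``P``
the excitation power in uW and ``t`` the dwell time. The emission long-pass
filter of the excitation line is applied as a hard cutoff (no emission
below the edge); the detector-side ``background`` is not filtered. Noise is
Poisson on expected counts followed by additive Gaussian read noise.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .photophysics import (
    DEFAULT_CONCENTRATIONS,
    PhotophysRecord,
    StainConfig,
    epsilon_at,
    load_photophysics,
)
from .spectral import EmissionSpectrum, SpectralCube, WavelengthAxis

#: Long-pass edge (nm) of the emission filter used with each laser line.
#: The 465/488 nm lines share a 532 nm long-pass that becomes transparent
#: around 539 nm; the 560 and 633 nm lines use long-pass filters with edges
#: taken at 566 and 652 nm respectively.
EMISSION_LONGPASS_NM = {465.0: 539.0, 488.0: 539.0, 560.0: 566.0, 633.0: 652.0}

#: Laser line each dye/ion is designated to (its optimal excitation).
DESIGNATED_EXCITATION = {
    "F18": 488.0,
    "Tb": 488.0,
    "MitoTracker Red": 560.0,
    "ATTO647N": 633.0,
    "Eu": 465.0,
}


class PlanEntry(NamedTuple):
    """One scan of the four-quadrant imaging plan."""

    excitation_nm: float
    power_uW: float
    quadrant: str  # one of "ne", "nw", "se", "sw"


#: Default excitation plan: wavelengths and powers of the four laser lines,
#: one image quadrant each.
DEFAULT_PLAN = (
    PlanEntry(465.0, 2.0, "nw"),
    PlanEntry(488.0, 7.2, "ne"),
    PlanEntry(560.0, 1.2, "sw"),
    PlanEntry(633.0, 2.9, "se"),
)

_QUADRANTS = ("ne", "nw", "se", "sw")


@dataclass
class BleachModel:
    """Bi-exponential photobleaching: a1*exp(-t/tau1) + a2*exp(-t/tau2) + b.

    Amplitudes and baseline sum to 1 so the factor starts at 1 at t=0.
    """

    a1: float
    tau1_s: float
    a2: float = 0.0
    tau2_s: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if min(self.a1, self.a2, self.baseline) < 0:
            raise ValueError("amplitudes and baseline must be >= 0")
        if self.tau1_s <= 0 or self.tau2_s <= 0:
            raise ValueError("time constants must be > 0")
        total = self.a1 + self.a2 + self.baseline
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"a1 + a2 + baseline must sum to 1, got {total}")

    def factor(self, elapsed_s) -> np.ndarray:
        t = np.asarray(elapsed_s, dtype=float)
        return (
            self.a1 * np.exp(-t / self.tau1_s)
            + self.a2 * np.exp(-t / self.tau2_s)
            + self.baseline
        )


NO_BLEACH = BleachModel(a1=0.0, tau1_s=1.0, a2=0.0, tau2_s=1.0, baseline=1.0)

#: Default photokinetic parameters, calibrated to the qualitative behaviour
#: of the three dyes under continuous single-pixel illumination: F18 loses
#: ~70% of its intensity in the first 10 s and levels out at background;
#: MitoTracker Red and ATTO647N both lose ~50% in a fast 5-10 s component,
#: with MitoTracker Red essentially gone by ~40 s and ATTO647N surviving
#: toward ~100 s.
DEFAULT_BLEACH = {
    "F18": BleachModel(0.7, 4.0, 0.3, 25.0, 0.0),
    "MitoTracker Red": BleachModel(0.5, 7.0, 0.5, 15.0, 0.0),
    "ATTO647N": BleachModel(0.5, 7.0, 0.5, 40.0, 0.0),
}


@dataclass
class Zeolite:
    """A micron-scale doped zeolite particle.

    ``loading`` is the effective dopant concentration in uM-equivalents
    (local lanthanide concentrations in an exchanged zeolite are of order
    1 M = 1e6 uM). The annular profile renders a bright rim and darker
    core, as doped particles appear under the microscope: weight 1 within
    ``rim_width_um`` of the surface, ``core_level`` inside, 0 outside.
    """

    dopant: PhotophysRecord
    center_um: tuple = (0.0, 0.0)
    radius_um: float = 1.5
    loading: float = 5.0e5
    rim_width_um: float = 0.5
    core_level: float = 0.25

    def loading_weight(self, x_um: float, y_um: float) -> float:
        r = float(np.hypot(x_um - self.center_um[0], y_um - self.center_um[1]))
        if r > self.radius_um:
            return 0.0
        if r >= self.radius_um - self.rim_width_um:
            return 1.0
        return self.core_level


@dataclass
class NoiseModel:
    poisson: bool = True
    read_sigma: float = 1.0


@dataclass
class SceneConfig:
    """Complete synthetic model-system description."""

    nx: int = 10
    ny: int = 10
    pixel_size_um: float = 0.5
    film_stains: list = field(default_factory=list)
    zeolites: list = field(default_factory=list)
    background_level: float = 2.0
    excitation_plan: tuple = DEFAULT_PLAN
    noise: NoiseModel = field(default_factory=NoiseModel)
    bleach_params: dict = field(default_factory=lambda: dict(DEFAULT_BLEACH))
    photon_scale: float = 1.0
    integration_time_s: float = 1.0
    axis: WavelengthAxis = field(default_factory=WavelengthAxis.default)
    #: If True, scans assume continuous illumination of the whole field and
    #: the bleach factor advances by 1 s per raster pixel. The default
    #: (False) models point-scanning confocal dwell: every scan pixel is
    #: fresh film, which is what the four-quadrant imaging plan is designed
    #: to preserve. Single-pixel bleach series always accumulate exposure.
    cumulative_scan_bleaching: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("scene needs at least one pixel")
        for entry in self.excitation_plan:
            if entry.quadrant not in _QUADRANTS:
                raise ValueError(f"unknown quadrant {entry.quadrant!r}")

    def plan_entry(self, excitation_nm: float) -> PlanEntry:
        for entry in self.excitation_plan:
            if abs(entry.excitation_nm - excitation_nm) < 0.5:
                return entry
        raise ValueError(
            f"excitation {excitation_nm} nm is not in the scene's plan "
            f"({[e.excitation_nm for e in self.excitation_plan]})"
        )


def single_dye_scene(
    dye: str,
    dopants: tuple = ("Eu",),
    concentration_uM: float | None = None,
    seed: int = 0,
    **overrides,
) -> SceneConfig:
    """Standard single-dye sample: one stained film + doped zeolite(s) at
    the shared corner of the four imaging quadrants."""
    records = load_photophysics()
    if dye not in records:
        raise KeyError(f"unknown dye {dye!r}; have {sorted(records)}")
    conc = (
        DEFAULT_CONCENTRATIONS.get(dye, 0.1)
        if concentration_uM is None
        else concentration_uM
    )
    stains = [StainConfig(record=records[dye], concentration_uM=conc)]
    zeolites = [Zeolite(dopant=records[d]) for d in dopants]
    return SceneConfig(
        film_stains=stains, zeolites=zeolites, seed=seed, **overrides
    )


def background_scene(scene: SceneConfig) -> SceneConfig:
    """The matching dye-free reference sample: all stain concentrations and
    dopant loadings zeroed, detector background retained. Idempotent."""
    stains = [replace(s, concentration_uM=0.0) for s in scene.film_stains]
    zeolites = [replace(z, loading=0.0) for z in scene.zeolites]
    return replace(
        scene,
        film_stains=stains,
        zeolites=zeolites,
        bleach_params=copy.deepcopy(scene.bleach_params),
    )


def _quadrant_origin(quadrant: str, width_um: float, height_um: float) -> tuple:
    # image top-left corner in global um; the global origin (default zeolite
    # centre) is a corner of every quadrant's imaging area
    return {
        "ne": (0.0, 0.0),
        "nw": (-width_um, 0.0),
        "se": (0.0, -height_um),
        "sw": (-width_um, -height_um),
    }[quadrant]


def _pixel_center_um(scene: SceneConfig, x: int, y: int, quadrant: str) -> tuple:
    ox, oy = _quadrant_origin(
        quadrant, scene.nx * scene.pixel_size_um, scene.ny * scene.pixel_size_um
    )
    return (
        ox + (x + 0.5) * scene.pixel_size_um,
        oy + (y + 0.5) * scene.pixel_size_um,
    )


def _bleach_factor(scene: SceneConfig, name: str, elapsed_s: float) -> float:
    model = scene.bleach_params.get(name)
    return 1.0 if model is None else float(model.factor(elapsed_s))


def expected_pixel_intensity(
    scene: SceneConfig,
    x: int,
    y: int,
    excitation_nm: float,
    power_uW: float | None = None,
    elapsed_s: float = 0.0,
) -> np.ndarray:
    """Noise-free expected counts per wavelength sample at one pixel."""
    if not (0 <= x < scene.nx and 0 <= y < scene.ny):
        raise ValueError(f"pixel ({x}, {y}) outside {scene.nx} x {scene.ny} scene")
    entry = scene.plan_entry(excitation_nm)
    if power_uW is None:
        power_uW = entry.power_uW
    wl = scene.axis.values
    emitted = np.zeros_like(wl)
    k = scene.photon_scale * power_uW * scene.integration_time_s

    for stain in scene.film_stains:
        if stain.concentration_uM <= 0:
            continue
        rec = stain.record
        amp = (
            k
            * stain.concentration_uM
            * epsilon_at(rec, entry.excitation_nm)
            * rec.qy
            * _bleach_factor(scene, rec.name, elapsed_s)
        )
        if amp > 0:
            emitted += amp * rec.emission_shape.sample(wl)

    gx, gy = _pixel_center_um(scene, x, y, entry.quadrant)
    for zeolite in scene.zeolites:
        weight = zeolite.loading_weight(gx, gy)
        if weight <= 0 or zeolite.loading <= 0:
            continue
        rec = zeolite.dopant
        amp = (
            k
            * zeolite.loading
            * weight
            * epsilon_at(rec, entry.excitation_nm)
            * rec.qy
            * _bleach_factor(scene, rec.name, elapsed_s)
        )
        if amp > 0:
            emitted += amp * rec.emission_shape.sample(wl)

    # hard long-pass cutoff on emitted light; detector background unfiltered
    edge = EMISSION_LONGPASS_NM.get(float(entry.excitation_nm))
    if edge is not None:
        emitted[wl < edge] = 0.0
    return scene.background_level + emitted


def pixel_spectrum(
    scene: SceneConfig,
    x: int,
    y: int,
    excitation_nm: float,
    power_uW: float | None = None,
    elapsed_s: float = 0.0,
) -> EmissionSpectrum:
    """Noise-free emission spectrum of one pixel (the forward model)."""
    return EmissionSpectrum(
        axis=scene.axis,
        intensity=expected_pixel_intensity(
            scene, x, y, excitation_nm, power_uW, elapsed_s
        ),
    )


def _apply_noise(
    expected: np.ndarray, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    # unclipped: read noise may take offset-subtracted counts slightly
    # below zero, and clipping would bias replicate means upward
    out = np.asarray(expected, dtype=float)
    if noise.poisson:
        out = rng.poisson(out).astype(float)
    if noise.read_sigma > 0:
        out = out + rng.normal(0.0, noise.read_sigma, size=out.shape)
    return out


def simulate_scan(
    scene: SceneConfig, plan_entry, seed: int | None = None
) -> SpectralCube:
    """Simulate one raster scan of the plan.

    Pixels are visited in raster order (x fastest). With
    ``cumulative_scan_bleaching`` the elapsed illumination time accumulates
    at ``integration_time_s`` per pixel and drives the per-stain bleach
    factor; by default each pixel is fresh (confocal dwell). Deterministic
    given the seed (defaults to the scene's seed).
    """
    if isinstance(plan_entry, (int, float)):
        plan_entry = scene.plan_entry(float(plan_entry))
    entry = scene.plan_entry(plan_entry.excitation_nm)
    rng = np.random.default_rng(scene.seed if seed is None else seed)
    data = np.empty((scene.ny, scene.nx, len(scene.axis)))
    idx = 0
    for y in range(scene.ny):
        for x in range(scene.nx):
            elapsed = (
                idx * scene.integration_time_s
                if scene.cumulative_scan_bleaching
                else 0.0
            )
            expected = expected_pixel_intensity(
                scene,
                x,
                y,
                entry.excitation_nm,
                entry.power_uW,
                elapsed_s=elapsed,
            )
            data[y, x] = _apply_noise(expected, scene.noise, rng)
            idx += 1
    return SpectralCube(
        data=data,
        axis=scene.axis,
        pixel_size_um=scene.pixel_size_um,
        excitation_nm=entry.excitation_nm,
        excitation_power_uW=entry.power_uW,
        integration_time_s=scene.integration_time_s,
    )


def simulate_bleach_series(
    scene: SceneConfig,
    pixel: tuple,
    excitation_nm: float,
    n_frames: int = 100,
    dt_s: float = 1.0,
    seed: int | None = None,
) -> list:
    """Accelerated single-pixel bleaching experiment: the emission spectrum
    of one continuously illuminated pixel recorded every ``dt_s`` seconds."""
    x, y = pixel
    rng = np.random.default_rng(scene.seed if seed is None else seed)
    series = []
    for i in range(n_frames):
        expected = expected_pixel_intensity(
            scene, x, y, excitation_nm, elapsed_s=i * dt_s
        )
        # raw spectra are nonnegative by contract; clip the rare negative
        # read-noise excursion at zero
        series.append(
            EmissionSpectrum(
                axis=scene.axis,
                intensity=np.clip(_apply_noise(expected, scene.noise, rng), 0.0, None),
            )
        )
    return series


def zeolite_mask(scene: SceneConfig, plan_entry) -> np.ndarray:
    """Ground-truth boolean image: True where a pixel centre falls on a
    zeolite particle in the given scan's quadrant."""
    if isinstance(plan_entry, (int, float)):
        plan_entry = scene.plan_entry(float(plan_entry))
    mask = np.zeros((scene.ny, scene.nx), dtype=bool)
    for y in range(scene.ny):
        for x in range(scene.nx):
            gx, gy = _pixel_center_um(scene, x, y, plan_entry.quadrant)
            mask[y, x] = any(
                z.loading_weight(gx, gy) > 0 for z in scene.zeolites
            )
    return mask
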