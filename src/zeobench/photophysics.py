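"""Photophysical constants and brightness / photon-budget arithmetic.

The package ships the measured photophysical properties of the three dyes
(F18, MitoTracker Red, ATTO647N) and the two lanthanide ions (Eu3+, Tb3+)
used in the zeolite/PVA model system: quantum yield, molar absorptivity at
the absorption maximum and at the four laser lines (465/488/560/633 nm),
emission maximum and excited-state lifetime.

Brightness — the product of quantum yield and molar absorptivity at the
excitation wavelength — predicts per-molecule emission under non-saturating
excitation. Combined with the excited-state turnover rate (1/lifetime) it
yields the per-molecule photon-budget ratio between emitters, e.g. the
>1e11 advantage of a fluorescein dye over directly excited Eu(III).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

from .shapes import DEFAULT_EMISSION_SHAPES, DEFAULT_EXCITATION_SHAPES

#: Laser lines of the four-excitation imaging plan (nm).
LASER_LINES = (465.0, 488.0, 560.0, 633.0)

#: Film staining concentrations of the model system (uM).
DEFAULT_CONCENTRATIONS = {"F18": 150.0, "MitoTracker Red": 0.1, "ATTO647N": 0.1}

_LINE_MATCH_TOL_NM = 0.25


@dataclass
class PhotophysRecord:
    """One emitter's photophysical constants (one table row).

    ``eps_at`` maps an excitation wavelength in nm to the tabulated molar
    absorptivity in M^-1 cm^-1; these exact laser-line values take
    precedence over interpolation through ``excitation_shape``.
    """

    name: str
    qy: float
    eps_max: float
    eps_max_wavelength: float
    eps_at: dict = field(default_factory=dict)
    emission_max_nm: float = float("nan")
    excited_state_lifetime_ns: float = float("nan")
    excitation_shape: object = None
    emission_shape: object = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.qy <= 1.0:
            raise ValueError(f"{self.name}: quantum yield must be in [0, 1]")
        if self.eps_max < 0:
            raise ValueError(f"{self.name}: eps_max must be >= 0")
        self.eps_at = {float(k): float(v) for k, v in self.eps_at.items()}
        for wl, eps in self.eps_at.items():
            if eps < 0:
                raise ValueError(f"{self.name}: eps({wl}) must be >= 0")
            if eps > self.eps_max * (1 + 1e-9):
                raise ValueError(f"{self.name}: eps({wl}) exceeds eps_max")


def load_photophysics(with_shapes: bool = True) -> dict:
    """Packaged photophysics table as ``{name: PhotophysRecord}``.

    With ``with_shapes=True`` the default synthetic excitation/emission
    shapes are attached; pass False to attach measured shapes yourself.
    """
    text = resources.files("zeobench.data").joinpath("photophysics.json").read_text()
    records = {}
    for name, row in json.loads(text).items():
        rec = PhotophysRecord(name=name, **row)
        if with_shapes:
            rec.excitation_shape = DEFAULT_EXCITATION_SHAPES.get(name)
            rec.emission_shape = DEFAULT_EMISSION_SHAPES.get(name)
        records[name] = rec
    return records


def epsilon_at(record: PhotophysRecord, wavelength_nm: float) -> float:
    """Molar absorptivity at a wavelength (M^-1 cm^-1).

    Tabulated laser-line values are returned verbatim; other wavelengths
    use eps_max × the peak-normalised excitation shape. Outside any known
    support the result is 0 with a warning.
    """
    for wl, eps in record.eps_at.items():
        if abs(wl - wavelength_nm) <= _LINE_MATCH_TOL_NM:
            return eps
    if record.excitation_shape is not None:
        return float(record.eps_max * record.excitation_shape.density(wavelength_nm))
    warnings.warn(
        f"{record.name}: no absorptivity information at {wavelength_nm} nm; "
        "returning 0",
        stacklevel=2,
    )
    return 0.0


def brightness(record: PhotophysRecord, wavelength_nm: float) -> float:
    """Quantum yield × molar absorptivity at the excitation wavelength."""
    return record.qy * epsilon_at(record, wavelength_nm)


def photon_budget_ratio(
    a: PhotophysRecord,
    b: PhotophysRecord,
    wavelength_a_nm: float,
    wavelength_b_nm: float,
) -> float:
    """Per-molecule emission-rate advantage of ``a`` over ``b``.

    (brightness_a / brightness_b) × (lifetime_b / lifetime_a): the
    absorption-brightness ratio times the excited-state turnover ratio.
    """
    if not (a.excited_state_lifetime_ns > 0 and b.excited_state_lifetime_ns > 0):
        raise ValueError("both excited-state lifetimes must be > 0")
    bright_a = brightness(a, wavelength_a_nm)
    bright_b = brightness(b, wavelength_b_nm)
    if bright_b <= 0:
        raise ValueError(f"{b.name} has zero brightness at {wavelength_b_nm} nm")
    if bright_a <= 0:
        raise ValueError(f"{a.name} has zero brightness at {wavelength_a_nm} nm")
    return (bright_a / bright_b) * (
        b.excited_state_lifetime_ns / a.excited_state_lifetime_ns
    )


@dataclass
class StainConfig:
    """A film stain: emitter record plus its concentration in the film."""

    record: PhotophysRecord
    concentration_uM: float

    def __post_init__(self) -> None:
        if self.concentration_uM < 0:
            raise ValueError("concentration must be >= 0")


def concentration_ratio(a: StainConfig, b: StainConfig) -> float:
    """Molarity ratio a/b (e.g. 150 uM F18 vs 0.1 uM MitoTracker Red = 1500)."""
    if b.concentration_uM <= 0:
        raise ValueError("reference stain concentration must be > 0")
    return a.concentration_uM / b.concentration_uM
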