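"""Interchange formats, manifests and the end-to-end pipeline.

Formats
-------
* Spectrum: two-column plain text (wavelength_nm, intensity), ``#`` header.
* Cube: multi-frame TIFF (one frame per wavelength sample, float32) plus a
  JSON sidecar with the wavelength axis and acquisition metadata; also a
  long-format TSV (x, y, wavelength_nm, intensity).
* Filter sets: JSON list of {name, lo_nm, hi_nm, transmission}.
* Manifest: JSON index of data files with their role in the analysis.

Pixel coordinates are 0-based, (0, 0) top-left, x rightward, y downward,
in every reader and writer. Cube data is stored as float32; round-trips
are lossless at that precision.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .bleaching import (
    DEFAULT_WINDOWS,
    fit_decay,
    fraction_lost,
    minmax_normalize,
    trace_from_series,
)
from .channels import FilterSet, builtin_filter_set, channel_signal_table
from .crosstalk import bleedthrough_report, build_crosstalk_matrix
from .scene import (
    DESIGNATED_EXCITATION,
    background_scene,
    simulate_bleach_series,
    simulate_scan,
    single_dye_scene,
)
from .spectral import EmissionSpectrum, FilterChannel, SpectralCube, WavelengthAxis


class ConfigError(ValueError):
    """Invalid pipeline/CLI configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Malformed or inconsistent data files (CLI exit code 3)."""


# ---------------------------------------------------------------- spectra


def write_spectrum(spectrum: EmissionSpectrum, path) -> None:
    header = "wavelength_nm\tintensity"
    if spectrum.background_subtracted:
        header += "\n background_subtracted"
    np.savetxt(
        path,
        np.column_stack([spectrum.axis.values, spectrum.intensity]),
        fmt="%.9g",
        delimiter="\t",
        header=header,
    )


def read_spectrum(path) -> EmissionSpectrum:
    text = Path(path).read_text()
    subtracted = "background_subtracted" in text
    try:
        arr = np.loadtxt(path, comments="#", delimiter="\t", ndmin=2)
        return EmissionSpectrum(
            axis=WavelengthAxis(arr[:, 0]),
            intensity=arr[:, 1],
            background_subtracted=subtracted,
        )
    except (ValueError, IndexError) as exc:
        raise DataError(f"cannot parse spectrum file {path}: {exc}") from exc


# ------------------------------------------------------------------ cubes


def write_cube(cube: SpectralCube, path, sidecar_path=None) -> None:
    path = Path(path)
    sidecar_path = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    # frame-per-wavelength stack
    tifffile.imwrite(
        path,
        np.moveaxis(cube.data, 2, 0).astype(np.float32),
        photometric="minisblack",
    )
    sidecar = {
        "wavelengths_nm": cube.axis.values.tolist(),
        "pixel_size_um": cube.pixel_size_um,
        "excitation_nm": cube.excitation_nm,
        "excitation_power_uW": cube.excitation_power_uW,
        "integration_time_s": cube.integration_time_s,
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_cube(path, sidecar_path=None) -> SpectralCube:
    path = Path(path)
    sidecar_path = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    try:
        meta = json.loads(sidecar_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise DataError(f"cannot read cube sidecar {sidecar_path}: {exc}") from exc
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    wavelengths = meta["wavelengths_nm"]
    if stack.shape[0] != len(wavelengths):
        raise DataError(
            f"cube {path} has {stack.shape[0]} frames but sidecar lists "
            f"{len(wavelengths)} wavelengths"
        )
    return SpectralCube(
        data=np.moveaxis(stack.astype(float), 0, 2),
        axis=WavelengthAxis(np.asarray(wavelengths)),
        pixel_size_um=float(meta.get("pixel_size_um", 0.5)),
        excitation_nm=float(meta.get("excitation_nm", float("nan"))),
        excitation_power_uW=float(meta.get("excitation_power_uW", float("nan"))),
        integration_time_s=float(meta.get("integration_time_s", 1.0)),
    )


def cube_to_long_tsv(cube: SpectralCube, path) -> None:
    ny, nx, nw = cube.data.shape
    yy, xx, ww = np.meshgrid(
        np.arange(ny), np.arange(nx), np.arange(nw), indexing="ij"
    )
    pd.DataFrame(
        {
            "x": xx.ravel(),
            "y": yy.ravel(),
            "wavelength_nm": cube.axis.values[ww.ravel()],
            "intensity": cube.data.ravel(),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.9g")


def cube_from_long_tsv(path, **metadata) -> SpectralCube:
    df = pd.read_csv(path, sep="\t")
    required = {"x", "y", "wavelength_nm", "intensity"}
    if not required.issubset(df.columns):
        raise DataError(
            f"long-format cube {path} is missing columns "
            f"{sorted(required - set(df.columns))}"
        )
    wavelengths = np.sort(df["wavelength_nm"].unique())
    nx = int(df["x"].max()) + 1
    ny = int(df["y"].max()) + 1
    data = np.zeros((ny, nx, wavelengths.size))
    wl_index = {w: i for i, w in enumerate(wavelengths)}
    for row in df.itertuples(index=False):
        data[int(row.y), int(row.x), wl_index[row.wavelength_nm]] = row.intensity
    return SpectralCube(data=data, axis=WavelengthAxis(wavelengths), **metadata)


# ------------------------------------------------------------ filter sets


def write_filter_set(filterset: FilterSet, path) -> None:
    Path(path).write_text(
        json.dumps([dataclasses.asdict(ch) for ch in filterset], indent=1)
    )


def read_filter_set(path, name=None) -> FilterSet:
    try:
        channels = [FilterChannel(**c) for c in json.loads(Path(path).read_text())]
    except (json.JSONDecodeError, TypeError, ValueError) as exc:
        raise DataError(f"cannot parse filter set {path}: {exc}") from exc
    return FilterSet(name=name or Path(path).stem, channels=channels)


def resolve_filter_set(spec: str) -> FilterSet:
    """``edmund``/``chroma`` or a path to a JSON filter-set file."""
    try:
        return builtin_filter_set(spec)
    except KeyError:
        if Path(spec).exists():
            return read_filter_set(spec)
        raise ConfigError(
            f"unknown filter set {spec!r}: not a builtin name and not a file"
        ) from None


# -------------------------------------------------------------- manifests

MANIFEST_VERSION = "1"


@dataclass
class ManifestEntry:
    path: str
    kind: str  # cube | spectrum | table
    role: str = "signal"  # signal | background
    excitation_nm: float | None = None
    scene_label: str | None = None


@dataclass
class Manifest:
    entries: list = field(default_factory=list)
    format_version: str = MANIFEST_VERSION

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "format_version": self.format_version,
                    "entries": [dataclasses.asdict(e) for e in self.entries],
                },
                indent=1,
            )
        )

    @classmethod
    def read(cls, path) -> "Manifest":
        try:
            doc = json.loads(Path(path).read_text())
            entries = [ManifestEntry(**e) for e in doc["entries"]]
        except (OSError, json.JSONDecodeError, KeyError, TypeError) as exc:
            raise DataError(f"cannot read manifest {path}: {exc}") from exc
        manifest = cls(entries=entries, format_version=doc.get("format_version", "?"))
        base = Path(path).parent
        for e in manifest.entries:
            if not (base / e.path).exists() and not Path(e.path).exists():
                raise DataError(f"manifest {path}: missing file {e.path}")
        return manifest

    def load_cubes(self, base_dir) -> tuple:
        """Return (signal cubes {(label, exc): cube}, background {exc: cube})."""
        base = Path(base_dir)
        signal, background = {}, {}
        for e in self.entries:
            if e.kind != "cube":
                continue
            p = base / e.path if (base / e.path).exists() else Path(e.path)
            cube = read_cube(p)
            exc = e.excitation_nm if e.excitation_nm is not None else cube.excitation_nm
            if e.role == "background":
                background[exc] = cube
            else:
                signal[(e.scene_label or p.stem, exc)] = cube
        return signal, background


# ----------------------------------------------------------------- config


def load_config(path) -> dict:
    """Pipeline configuration from YAML or JSON."""
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"config {path} must be a mapping")
    return doc


# --------------------------------------------------------------- pipeline


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


def run_pipeline(config: dict | None = None, out_dir=".", seed: int | None = None) -> dict:
    """End-to-end run: simulate -> channels -> crosstalk -> bleach.

    Simulates one single-dye scene per dye plus the dye-free background,
    writes all cubes (TIFF + sidecar) with a manifest, the channel signal
    tables and crosstalk flag reports for the requested filter sets, the
    bleaching traces and fits, and a structured log. Deterministic given
    the seed: identical runs produce byte-identical tables.
    """
    config = dict(config or {})
    out = Path(out_dir)
    dyes = config.get("dyes", ["F18", "MitoTracker Red", "ATTO647N"])
    filtersets = config.get("filtersets", ["edmund", "chroma"])
    if seed is None:
        seed = int(config.get("seed", 0))
    scene_overrides = config.get("scene", {})
    if not isinstance(scene_overrides, dict):
        raise ConfigError("'scene' section must be a mapping")

    stage = "simulate"
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / "cubes").mkdir(exist_ok=True)
        scenes = {
            dye: single_dye_scene(dye, seed=seed, **scene_overrides) for dye in dyes
        }
        bg_scene = background_scene(next(iter(scenes.values())))
        manifest = Manifest()
        cubes_by_dye: dict = {}
        background_cubes: dict = {}
        counter = 0
        for dye, scn in scenes.items():
            cubes_by_dye[dye] = {}
            for entry in scn.excitation_plan:
                cube = simulate_scan(scn, entry, seed=(seed * 1000003 + counter) % 2**31)
                counter += 1
                name = f"cubes/{dye.replace(' ', '_')}_{int(entry.excitation_nm)}.tiff"
                write_cube(cube, out / name)
                manifest.entries.append(
                    ManifestEntry(
                        path=name,
                        kind="cube",
                        role="signal",
                        excitation_nm=entry.excitation_nm,
                        scene_label=dye,
                    )
                )
                cubes_by_dye[dye][entry.excitation_nm] = cube
        for entry in bg_scene.excitation_plan:
            cube = simulate_scan(bg_scene, entry, seed=(seed * 1000003 + counter) % 2**31)
            counter += 1
            name = f"cubes/background_{int(entry.excitation_nm)}.tiff"
            write_cube(cube, out / name)
            manifest.entries.append(
                ManifestEntry(
                    path=name,
                    kind="cube",
                    role="background",
                    excitation_nm=entry.excitation_nm,
                    scene_label="background",
                )
            )
            background_cubes[entry.excitation_nm] = cube
        manifest.write(out / "manifest.json")
    except (ConfigError, KeyError) as exc:
        raise PipelineError(stage, exc) from exc

    results: dict = {"seed": seed, "out_dir": str(out)}
    any_scene = next(iter(scenes.values()))

    stage = "channels"
    try:
        for fs_name in filtersets:
            fs = resolve_filter_set(fs_name)
            cubes = {
                (dye, exc): cube
                for dye, per in cubes_by_dye.items()
                for exc, cube in per.items()
            }
            table = channel_signal_table(
                cubes, background_cubes, fs, scene=any_scene
            )
            table.to_csv(out / f"channels_{fs.name}.tsv", sep="\t", index=False)
    except ValueError as exc:
        raise PipelineError(stage, exc) from exc

    stage = "crosstalk"
    try:
        flag_reports = {}
        for fs_name in filtersets:
            fs = resolve_filter_set(fs_name)
            matrix = build_crosstalk_matrix(
                cubes_by_dye, background_cubes, fs, scene=any_scene
            )
            matrix.table.to_csv(out / f"crosstalk_{fs.name}.tsv", sep="\t", index=False)
            flag_reports[fs.name] = bleedthrough_report(matrix)
        (out / "crosstalk_flags.json").write_text(
            json.dumps(flag_reports, indent=1, sort_keys=True)
        )
        results["crosstalk_flags"] = flag_reports
    except ValueError as exc:
        raise PipelineError(stage, exc) from exc

    stage = "bleach"
    try:
        bleach_report = {}
        traces = []
        for i, (dye, scn) in enumerate(scenes.items()):
            exc_nm = DESIGNATED_EXCITATION.get(dye, scn.excitation_plan[0].excitation_nm)
            series = simulate_bleach_series(
                scn,
                pixel=(scn.nx - 1, scn.ny - 1),
                excitation_nm=exc_nm,
                seed=(seed * 1000003 + 9001 + i) % 2**31,
            )
            window = DEFAULT_WINDOWS.get(dye, DEFAULT_WINDOWS["F18"])
            raw = trace_from_series(series, window)
            # fit the raw trace (detector background enters as the
            # baseline); normalize only for presentation and loss metrics
            fit = fit_decay(raw, n_components=2)
            trace = minmax_normalize(raw)
            bleach_report[dye] = {
                "window": [window.lo_nm, window.hi_nm],
                "fit": fit,
                "fraction_lost_10s": fraction_lost(trace, 10.0),
            }
            traces.append(
                pd.DataFrame(
                    {"dye": dye, "time_s": trace.times_s, "intensity": trace.intensity}
                )
            )
        pd.concat(traces).to_csv(out / "bleach_traces.tsv", sep="\t", index=False)
        (out / "bleach_fits.json").write_text(
            json.dumps(bleach_report, indent=1, sort_keys=True)
        )
        results["bleach"] = bleach_report
    except (ValueError, RuntimeError) as exc:
        raise PipelineError(stage, exc) from exc

    log = {
        "package": "zeobench",
        "version": __version__,
        "numpy": np.__version__,
        "seed": seed,
        "config": {"dyes": dyes, "filtersets": filtersets, "scene": scene_overrides},
    }
    (out / "log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    return results
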