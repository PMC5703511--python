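"""Virtual filter-channel signal extraction and pixel classification.

Reconstructs what a filter-based microscope would record from the
hyperspectral cubes: per-channel images via band integration, the
two-pixel background-subtracted fluorescent-signal statistic, contrast,
and the narrow-peak classifier that separates zeolite pixels (sharp
lanthanide lines) from film pixels (broad dye emission).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .spectral import (
    EmissionSpectrum,
    FilterChannel,
    SpectralCube,
    extract_channel_image,
)


@dataclass
class FilterSet:
    """Ordered list of emission filter channels emulating a commercial kit.

    Channels within a set may overlap (real kits do).
    """

    name: str
    channels: list

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("filter set needs at least one channel")

    def __iter__(self):
        return iter(self.channels)

    def channel(self, name: str) -> FilterChannel:
        for ch in self.channels:
            if ch.name == name:
                return ch
        raise KeyError(f"no channel {name!r} in filter set {self.name!r}")


def builtin_filter_set(name: str) -> FilterSet:
    """Packaged filter sets: ``edmund`` (FITC 539-556, TexasRed 604-644,
    Cy5 672-712) and ``chroma`` (FITC 539-550, mCherry 593-667, ATTO647N
    669-741). The green windows start at 539 nm because the 532 nm
    long-pass in the emission path only becomes transparent there."""
    text = resources.files("zeobench.data").joinpath("filter_sets.json").read_text()
    sets = json.loads(text)
    if name not in sets:
        raise KeyError(f"unknown filter set {name!r}; have {sorted(sets)}")
    return FilterSet(name=name, channels=[FilterChannel(**c) for c in sets[name]])


@dataclass
class SignalEstimate:
    """Background-subtracted signal statistic over a few pixels."""

    mean: float
    sd: float  # NaN when n_signal == 1
    n_signal: int
    n_background: int


def fluorescent_signal(signal_pixels, background_pixels) -> SignalEstimate:
    """The two-pixel fluorescent-signal statistic.

    The average of the background pixels is subtracted from each signal
    pixel; the mean and sample standard deviation (n-1 denominator) of the
    net values are returned. With the default n=2 the sd equals
    |net1 - net2| / sqrt(2).
    """
    sig = np.asarray(signal_pixels, dtype=float)
    bg = np.asarray(background_pixels, dtype=float)
    if sig.size == 0 or bg.size == 0:
        raise ValueError("signal and background pixel lists must be non-empty")
    net = sig - bg.mean()
    sd = float(net.std(ddof=1)) if sig.size > 1 else math.nan
    return SignalEstimate(
        mean=float(net.mean()), sd=sd, n_signal=sig.size, n_background=bg.size
    )


def farthest_film_pixels(
    cube: SpectralCube, n: int = 2, scene=None, excitation_nm: float | None = None
) -> list:
    """Default pixel selection: n film pixels farthest from any zeolite.

    With the generating scene available the geometric distance from the
    pixel centre to the nearest zeolite surface is used. Without it, the
    distance from the brightest pixel of the total-intensity image serves
    as a data-driven stand-in (the zeolite is the bright corner feature).
    Ties break in raster order.
    """
    ny, nx = cube.data.shape[:2]
    if scene is not None and scene.zeolites:
        from .scene import _pixel_center_um

        entry = scene.plan_entry(
            cube.excitation_nm if excitation_nm is None else excitation_nm
        )
        dist = np.empty((ny, nx))
        for y in range(ny):
            for x in range(nx):
                gx, gy = _pixel_center_um(scene, x, y, entry.quadrant)
                dist[y, x] = min(
                    np.hypot(gx - z.center_um[0], gy - z.center_um[1]) - z.radius_um
                    for z in scene.zeolites
                )
    else:
        total = cube.data.sum(axis=2)
        py, px = np.unravel_index(int(np.argmax(total)), total.shape)
        yy, xx = np.mgrid[0:ny, 0:nx]
        dist = np.hypot(yy - py, xx - px)
    order = np.argsort(-dist.ravel(), kind="stable")
    return [tuple(np.unravel_index(int(i), (ny, nx))) for i in order[:n]]


def channel_signal_table(
    cubes,
    background_cubes,
    filterset: FilterSet,
    pixel_selector=None,
    scene=None,
) -> pd.DataFrame:
    """Fluorescent signal per (scene label, excitation, channel).

    ``cubes`` maps ``(label, excitation_nm) -> SpectralCube`` of the dyed
    samples; ``background_cubes`` maps ``excitation_nm`` to the matching
    scan of the dye-free reference. Background pixel values are read at the
    same positions in the background cube.
    """
    rows = []
    for (label, exc), cube in cubes.items():
        if exc not in background_cubes:
            raise ValueError(
                f"missing background cube for excitation {exc} nm (scene {label!r})"
            )
        bg_cube = background_cubes[exc]
        if pixel_selector is not None:
            pixels = pixel_selector(cube, exc)
        else:
            pixels = farthest_film_pixels(cube, n=2, scene=scene, excitation_nm=exc)
        for ch in filterset:
            img = extract_channel_image(cube, ch)
            bg_img = extract_channel_image(bg_cube, ch)
            est = fluorescent_signal(
                [img[y, x] for y, x in pixels],
                [bg_img[y, x] for y, x in pixels],
            )
            rows.append(
                {
                    "dye": label,
                    "excitation_nm": exc,
                    "channel": ch.name,
                    "mean": est.mean,
                    "sd": est.sd,
                    "n_signal": est.n_signal,
                    "n_background": est.n_background,
                }
            )
    return pd.DataFrame(rows)


def narrowness_statistic(
    spectrum: EmissionSpectrum, baseline_window_nm: float = 31.0
) -> float:
    """Peak residual above a median-filtered baseline, relative to the
    total integrated intensity (units 1/nm). Narrow lanthanide lines stand
    far above the running median; broad dye bands do not."""
    y = spectrum.intensity
    total = spectrum.total()
    if total <= 0:
        return 0.0
    size = max(3, int(round(baseline_window_nm / spectrum.axis.step)))
    if size % 2 == 0:
        size += 1
    baseline = median_filter(y, size=size, mode="nearest")
    return float(np.max(y - baseline) / total)


def classify_pixel(
    spectrum: EmissionSpectrum,
    threshold: float = 0.05,
    baseline_window_nm: float = 31.0,
) -> str:
    """Label a pixel ``"zeolite"`` (narrow line emission) or ``"film"``."""
    if not np.any(spectrum.intensity > 0):
        warnings.warn("all-zero spectrum; classifying as film", stacklevel=2)
        return "film"
    stat = narrowness_statistic(spectrum, baseline_window_nm)
    return "zeolite" if stat > threshold else "film"


def contrast(image, zeolite_pixels, film_pixels, background: float = 0.0) -> float:
    """Background-subtracted structure-to-surroundings intensity ratio.

    ``image`` may be a 2-D channel image with (y, x) pixel tuples or a 1-D
    profile with integer indices. A non-positive net film signal yields
    +inf with a warning (infinite-contrast flag).
    """
    vals = np.asarray(image, dtype=float)
    if len(zeolite_pixels) == 0 or len(film_pixels) == 0:
        raise ValueError("both pixel sets must be non-empty")

    def _mean(pixels):
        if vals.ndim == 2:
            return float(np.mean([vals[y, x] for y, x in pixels]))
        return float(np.mean([vals[i] for i in pixels]))

    net_z = _mean(zeolite_pixels) - background
    net_f = _mean(film_pixels) - background
    if net_f <= 0:
        warnings.warn(
            "film net signal <= 0; contrast reported as infinite", stacklevel=2
        )
        return math.inf
    return net_z / net_f
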