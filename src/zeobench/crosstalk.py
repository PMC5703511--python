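"""Cross-excitation spectra and emission bleed-through matrices.

Spectral crosstalk has two faces: cross-excitation (a laser line chosen
for one fluorophore also excites another) and emission bleed-through (an
off-target fluorophore's emission lands inside another channel's window).
Both are quantified here from single-dye scenes: a panel of background-
subtracted film spectra per excitation, and a (dye × excitation × channel)
matrix of fluorescent signals with flags wherever an off-target pairing
outshines the channel's designated (dye, excitation) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channels import FilterSet, channel_signal_table, farthest_film_pixels
from .spectral import EmissionSpectrum

#: Default designated (dye, excitation) pair per channel name, matching the
#: common filter-kit assignments: FITC <- F18 @ 488 nm, TexasRed/mCherry <-
#: MitoTracker Red @ 560 nm, Cy5/ATTO647N <- ATTO647N @ 633 nm.
DEFAULT_DESIGNATED = {
    "FITC": ("F18", 488.0),
    "TexasRed": ("MitoTracker Red", 560.0),
    "mCherry": ("MitoTracker Red", 560.0),
    "Cy5": ("ATTO647N", 633.0),
    "ATTO647N": ("ATTO647N", 633.0),
}


@dataclass
class CrosstalkMatrix:
    """Fluorescent signal per (dye, excitation, channel) plus the intended
    channel assignments."""

    table: pd.DataFrame
    filterset: FilterSet
    designated: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = {ch.name for ch in self.filterset}
        for ch_name, (dye, exc) in self.designated.items():
            if ch_name not in names:
                raise ValueError(f"designated channel {ch_name!r} not in filter set")
            hit = self.table[
                (self.table["channel"] == ch_name)
                & (self.table["dye"] == dye)
                & (np.isclose(self.table["excitation_nm"], exc))
            ]
            if hit.empty:
                raise ValueError(
                    f"designated pair ({dye}, {exc}) missing from the matrix "
                    f"for channel {ch_name!r}"
                )

    def value(self, dye: str, excitation_nm: float, channel: str) -> float:
        hit = self.table[
            (self.table["dye"] == dye)
            & (np.isclose(self.table["excitation_nm"], excitation_nm))
            & (self.table["channel"] == channel)
        ]
        if hit.empty:
            raise KeyError((dye, excitation_nm, channel))
        return float(hit["mean"].iloc[0])


def cross_excitation_panel(
    single_dye_cubes,
    background_cubes,
    scene=None,
    pixel_selector=None,
) -> dict:
    """Background-subtracted mean film-pixel spectrum per excitation for a
    single-dye sample (one dye per scene)."""
    panel = {}
    for exc, cube in single_dye_cubes.items():
        if exc not in background_cubes:
            raise ValueError(f"missing background cube for excitation {exc} nm")
        if pixel_selector is not None:
            pixels = pixel_selector(cube, exc)
        else:
            pixels = farthest_film_pixels(cube, n=2, scene=scene, excitation_nm=exc)
        mean_sig = np.mean([cube.data[y, x] for y, x in pixels], axis=0)
        mean_bg = np.mean(
            [background_cubes[exc].data[y, x] for y, x in pixels], axis=0
        )
        panel[exc] = EmissionSpectrum(
            axis=cube.axis,
            intensity=mean_sig - mean_bg,
            background_subtracted=True,
        )
    return panel


def build_crosstalk_matrix(
    cubes_by_dye,
    background_cubes,
    filterset: FilterSet,
    designated: dict | None = None,
    scene=None,
) -> CrosstalkMatrix:
    """Fill the (dye × excitation × channel) matrix from single-dye scans.

    ``cubes_by_dye`` maps ``dye -> {excitation_nm -> SpectralCube}``; all
    scenes must share geometry and the same background reference.
    """
    cubes = {
        (dye, exc): cube
        for dye, per_exc in cubes_by_dye.items()
        for exc, cube in per_exc.items()
    }
    table = channel_signal_table(cubes, background_cubes, filterset, scene=scene)
    if designated is None:
        present = set(table["dye"])
        designated = {
            ch.name: DEFAULT_DESIGNATED[ch.name]
            for ch in filterset
            if ch.name in DEFAULT_DESIGNATED
            and DEFAULT_DESIGNATED[ch.name][0] in present
        }
    return CrosstalkMatrix(table=table, filterset=filterset, designated=designated)


def bleedthrough_report(matrix: CrosstalkMatrix) -> dict:
    """Flag off-target signals that exceed their channel's designated pair.

    Returns ``{"flags": [...], "ratios": [...]}``. Each ratio entry holds
    off-target mean / designated mean with negative nets clipped to zero
    (and marked ``clipped``); a flag is raised whenever an off-target
    (dye, excitation) mean strictly exceeds the designated mean.
    """
    flags, ratios = [], []
    for ch_name, (d_dye, d_exc) in matrix.designated.items():
        designated_mean = matrix.value(d_dye, d_exc, ch_name)
        denom = max(designated_mean, 0.0)
        sub = matrix.table[matrix.table["channel"] == ch_name]
        for _, row in sub.iterrows():
            if row["dye"] == d_dye and np.isclose(row["excitation_nm"], d_exc):
                continue
            num = max(float(row["mean"]), 0.0)
            ratio = float("inf") if denom == 0 else num / denom
            ratios.append(
                {
                    "channel": ch_name,
                    "dye": row["dye"],
                    "excitation_nm": float(row["excitation_nm"]),
                    "ratio": ratio,
                    "clipped": bool(row["mean"] < 0 or designated_mean < 0),
                }
            )
            if float(row["mean"]) > designated_mean:
                flags.append(
                    {
                        "channel": ch_name,
                        "dye": row["dye"],
                        "excitation_nm": float(row["excitation_nm"]),
                        "off_target_mean": float(row["mean"]),
                        "designated": [d_dye, d_exc],
                        "designated_mean": designated_mean,
                    }
                )
    return {"flags": flags, "ratios": ratios}
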