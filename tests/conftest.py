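import numpy as np
import pytest

import zeobench as zb
from zeobench.scene import background_scene


@pytest.fixture(scope="session")
def records():
    return zb.load_photophysics()


@pytest.fixture(scope="session")
def axis():
    return zb.WavelengthAxis.default()


def make_quiet(scene):
    """Noise off, in place, for analytic comparisons."""
    scene.noise.poisson = False
    scene.noise.read_sigma = 0.0
    return scene


@pytest.fixture(scope="session")
def default_scenes():
    """Single-dye scenes (noise on) plus the dye-free background scene."""
    dyes = ["F18", "MitoTracker Red", "ATTO647N"]
    scenes = {d: zb.single_dye_scene(d, seed=11) for d in dyes}
    return scenes, background_scene(scenes["F18"])


@pytest.fixture(scope="session")
def default_cubes(default_scenes):
    """All 4-excitation scans of the default scenes, fixed seeds."""
    scenes, bg_scene = default_scenes
    cubes, backgrounds = {}, {}
    counter = 0
    for dye, scn in scenes.items():
        cubes[dye] = {}
        for entry in scn.excitation_plan:
            cubes[dye][entry.excitation_nm] = zb.simulate_scan(
                scn, entry, seed=500 + counter
            )
            counter += 1
    for entry in bg_scene.excitation_plan:
        backgrounds[entry.excitation_nm] = zb.simulate_scan(
            bg_scene, entry, seed=900 + counter
        )
        counter += 1
    return cubes, backgrounds
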