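"""Filter-set signals, background subtraction, classification, contrast."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import zeobench as zb
from zeobench.channels import farthest_film_pixels
from zeobench.photophysics import epsilon_at
from zeobench.scene import EMISSION_LONGPASS_NM, background_scene
from zeobench.spectral import band_weights

from conftest import make_quiet


class TestFluorescentSignal:
    def test_two_pixel_arithmetic(self):
        est = zb.fluorescent_signal([10.0, 12.0], [4.0, 4.0])
        assert est.mean == pytest.approx(7.0)
        assert est.sd == pytest.approx(math.sqrt(2))
        assert (est.n_signal, est.n_background) == (2, 2)

    def test_signal_equal_to_background_nets_zero(self):
        assert zb.fluorescent_signal([5.0, 5.0], [5.0, 5.0]).mean == 0.0

    def test_two_pixel_sd_is_net_difference_over_sqrt2(self):
        est = zb.fluorescent_signal([8.0, 3.0], [1.0, 1.0])
        assert est.sd == pytest.approx(abs(7.0 - 2.0) / math.sqrt(2))

    def test_single_signal_pixel_has_undefined_sd(self):
        est = zb.fluorescent_signal([10.0], [4.0, 4.0])
        assert math.isnan(est.sd)

    def test_empty_lists_raise(self):
        with pytest.raises(ValueError):
            zb.fluorescent_signal([], [1.0])
        with pytest.raises(ValueError):
            zb.fluorescent_signal([1.0], [])

    @given(shift=st.floats(-1e5, 1e5))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_shift_invariance(self, shift):
        sig, bg = [11.0, 14.0], [3.0, 5.0]
        a = zb.fluorescent_signal(sig, bg)
        b = zb.fluorescent_signal([s + shift for s in sig], [x + shift for x in bg])
        assert b.mean == pytest.approx(a.mean, abs=1e-6)
        assert b.sd == pytest.approx(a.sd, abs=1e-6)

    def test_noise_only_pixels_net_to_zero_in_expectation(self):
        rng = np.random.default_rng(3)
        sig = rng.normal(100.0, 2.0, 50)
        bg = rng.normal(100.0, 2.0, 50)
        est = zb.fluorescent_signal(sig, bg)
        assert abs(est.mean) < 3 * est.sd / math.sqrt(50)


class TestChannelSignalTable:
    def test_dye_free_scenes_give_near_zero_means(self, default_scenes):
        _, bg_scene = default_scenes
        fs = zb.builtin_filter_set("edmund")
        cubes = {
            ("none", e.excitation_nm): zb.simulate_scan(bg_scene, e, seed=31 + i)
            for i, e in enumerate(bg_scene.excitation_plan)
        }
        backgrounds = {
            e.excitation_nm: zb.simulate_scan(bg_scene, e, seed=131 + i)
            for i, e in enumerate(bg_scene.excitation_plan)
        }
        table = zb.channel_signal_table(cubes, backgrounds, fs)
        # pure noise: every mean within a few counting standard deviations
        widths = {ch.name: ch.hi_nm - ch.lo_nm for ch in fs}
        for _, row in table.iterrows():
            sigma = np.sqrt(2 * 2.0 * widths[row["channel"]])
            assert abs(row["mean"]) < 5 * sigma

    def test_missing_background_raises(self, default_cubes):
        cubes, backgrounds = default_cubes
        fs = zb.builtin_filter_set("edmund")
        partial = {k: v for k, v in backgrounds.items() if k != 560.0}
        with pytest.raises(ValueError, match="missing background"):
            zb.channel_signal_table(
                {("MitoTracker Red", 560.0): cubes["MitoTracker Red"][560.0]},
                partial,
                fs,
            )

    def test_noise_off_matches_analytic_forward_model(self):
        """Channel means equal c * eps * QY * P * t * k * window-overlap."""
        fs = zb.builtin_filter_set("edmund")
        for dye, exc in [("MitoTracker Red", 560.0), ("ATTO647N", 633.0)]:
            scn = make_quiet(zb.single_dye_scene(dye, seed=0))
            bg = background_scene(scn)
            cube = zb.simulate_scan(scn, exc)
            bg_cube = zb.simulate_scan(bg, exc)
            table = zb.channel_signal_table(
                {(dye, exc): cube}, {exc: bg_cube}, fs, scene=scn
            )
            stain = scn.film_stains[0]
            rec = stain.record
            entry = scn.plan_entry(exc)
            amp = (
                scn.photon_scale
                * stain.concentration_uM
                * epsilon_at(rec, exc)
                * rec.qy
                * entry.power_uW
                * scn.integration_time_s
            )
            shape = rec.emission_shape.sample(scn.axis.values).copy()
            shape[scn.axis.values < EMISSION_LONGPASS_NM[exc]] = 0.0
            for ch in fs:
                overlap = band_weights(scn.axis, ch.lo_nm, ch.hi_nm) @ shape
                expected = amp * overlap * ch.transmission
                got = float(
                    table[table["channel"] == ch.name]["mean"].iloc[0]
                )
                assert got == pytest.approx(expected, rel=1e-6, abs=1e-9)

    def test_f18_red_channel_exceeds_mitotracker_designated_signal(self, default_cubes):
        # the 1500x concentration advantage pushes the F18 emission tail
        # in the red window above MitoTracker Red's own designated signal
        cubes, backgrounds = default_cubes
        fs = zb.builtin_filter_set("edmund")
        table = zb.channel_signal_table(
            {
                ("F18", 488.0): cubes["F18"][488.0],
                ("MitoTracker Red", 560.0): cubes["MitoTracker Red"][560.0],
            },
            backgrounds,
            fs,
        )
        red = table[table["channel"] == "TexasRed"].set_index("dye")["mean"]
        assert red["F18"] > red["MitoTracker Red"]


class TestClassifier:
    def test_pure_lanthanide_lines_classify_as_zeolite(self, records, axis):
        for ion in ("Eu", "Tb"):
            shape = records[ion].emission_shape.sample(axis.values)
            spec = zb.EmissionSpectrum(axis, 1000.0 * shape)
            assert zb.classify_pixel(spec) == "zeolite"

    def test_pure_broad_dye_classifies_as_film(self, records, axis):
        for dye in ("F18", "MitoTracker Red", "ATTO647N"):
            shape = records[dye].emission_shape.sample(axis.values)
            spec = zb.EmissionSpectrum(axis, 1000.0 * shape)
            assert zb.classify_pixel(spec) == "film"

    def test_all_zero_spectrum_warns_film(self, axis):
        with pytest.warns(UserWarning, match="all-zero"):
            assert zb.classify_pixel(zb.EmissionSpectrum(axis, np.zeros(len(axis)))) == "film"

    def test_accuracy_on_labelled_synthetic_pixels(self):
        """>= 95% against generator truth on 200 mixed pixels at default SNR."""
        correct = total = 0
        for dye, dopant, exc in [
            ("ATTO647N", "Eu", 465.0),
            ("MitoTracker Red", "Tb", 488.0),
        ]:
            scn = zb.single_dye_scene(dye, dopants=(dopant,), seed=21)
            cube = zb.simulate_scan(scn, exc, seed=77)
            mask = zb.zeolite_mask(scn, exc)
            for y in range(scn.ny):
                for x in range(scn.nx):
                    label = zb.classify_pixel(
                        zb.EmissionSpectrum(cube.axis, np.clip(cube.data[y, x], 0, None))
                    )
                    truth = "zeolite" if mask[y, x] else "film"
                    correct += label == truth
                    total += 1
        assert total == 200
        assert correct / total >= 0.95

    def test_accuracy_degrades_as_lines_broaden(self, records, axis):
        """Narrowness-based separation weakens monotonically as the
        lanthanide line width approaches the dye band width."""
        dye_shape = records["ATTO647N"].emission_shape.sample(axis.values)

        def accuracy(line_fwhm):
            lines = tuple(
                (c, line_fwhm, r) for c, _, r in records["Eu"].emission_shape.lines
            )
            zeolite = zb.LineSetShape(lines).sample(axis.values)
            hits = 0
            hits += zb.classify_pixel(zb.EmissionSpectrum(axis, 1e4 * zeolite)) == "zeolite"
            hits += zb.classify_pixel(zb.EmissionSpectrum(axis, 1e4 * dye_shape)) == "film"
            return hits / 2

        accs = [accuracy(f) for f in (8.0, 16.0, 28.0, 40.0)]
        assert all(a2 <= a1 for a1, a2 in zip(accs, accs[1:]))
        assert accs[0] == 1.0


class TestContrast:
    def test_equal_means_give_unity(self):
        img = np.full((4, 4), 7.0)
        assert zb.contrast(img, [(0, 0)], [(3, 3)]) == pytest.approx(1.0)

    def test_net_ratio(self):
        img = np.array([[9.0, 5.0], [5.0, 5.0]])
        # background 1: zeolite net 8, film net 4
        assert zb.contrast(img, [(0, 0)], [(1, 1)], background=1.0) == pytest.approx(2.0)

    def test_nonpositive_film_net_flags_infinite(self):
        img = np.array([[9.0, 1.0], [1.0, 1.0]])
        with pytest.warns(UserWarning, match="infinite"):
            assert zb.contrast(img, [(0, 0)], [(1, 1)], background=2.0) == math.inf

    def test_red_channel_zeolite_contrast_far_exceeds_green(self):
        scn = make_quiet(zb.single_dye_scene("ATTO647N", dopants=("Eu",), seed=3))
        cube = zb.simulate_scan(scn, 465.0)
        mask = zb.zeolite_mask(scn, 465.0)
        zeolite_px = [tuple(p) for p in np.argwhere(mask)[:2]]
        film_px = farthest_film_pixels(cube, n=2, scene=scn)
        red = zb.extract_channel_image(cube, zb.FilterChannel("red", 604, 644))
        green = zb.extract_channel_image(cube, zb.FilterChannel("green", 539, 556))
        bg_red = 2.0 * 40.0  # background_level x window width
        bg_green = 2.0 * 17.0
        c_red = zb.contrast(red, zeolite_px, film_px, background=bg_red)
        with pytest.warns(UserWarning, match="infinite"):
            # no Eu lines or dye emission fall in the green window at all
            c_green = zb.contrast(green, zeolite_px, film_px, background=bg_green)
        assert c_red > 100 or c_green == math.inf


class TestPixelSelection:
    def test_scene_aware_selection_avoids_zeolite(self, default_scenes, default_cubes):
        scenes, _ = default_scenes
        cubes, _ = default_cubes
        scn = scenes["ATTO647N"]
        for exc in (465.0, 633.0):
            pixels = farthest_film_pixels(cubes["ATTO647N"][exc], n=2, scene=scn)
            mask = zb.zeolite_mask(scn, exc)
            for y, x in pixels:
                assert not mask[y, x]

    def test_data_driven_fallback_avoids_bright_corner(self, default_cubes):
        cubes, _ = default_cubes
        cube = cubes["ATTO647N"][465.0]
        pixels = farthest_film_pixels(cube, n=2)
        total = cube.data.sum(axis=2)
        peak = np.unravel_index(np.argmax(total), total.shape)
        for y, x in pixels:
            assert np.hypot(y - peak[0], x - peak[1]) > 5
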