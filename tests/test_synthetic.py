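"""Synthetic scene generator: determinism, ground-truth rendering, and the
structural contracts of backgrounds and crab targets."""

import numpy as np
import pytest

import crabcamo as cc
from crabcamo import synthetic
from crabcamo.spectra import WAVELENGTHS, normalized_catches


def trapezoid_catch_oracle(reflectance, sensitivity, illuminant=None):
    """Independent quadrature oracle: explicit np.trapezoid ratio."""
    I = np.ones_like(WAVELENGTHS) if illuminant is None else illuminant
    num = np.trapezoid(reflectance * I * sensitivity, WAVELENGTHS)
    den = np.trapezoid(I * sensitivity, WAVELENGTHS)
    return num / den


class TestSpectrumLibrary:
    def test_seeded_determinism(self):
        a = cc.make_spectrum_library(50, seed=1)
        b = cc.make_spectrum_library(50, seed=1)
        np.testing.assert_array_equal(a, b)
        c = cc.make_spectrum_library(50, seed=2)
        assert not np.array_equal(a, c)

    def test_clipping_contract(self):
        lib = cc.make_spectrum_library(200, seed=3)
        assert lib.min() >= 0.01 and lib.max() <= 0.99

    def test_too_few_spectra_rejected(self):
        with pytest.raises(ValueError):
            cc.make_spectrum_library(1, seed=0)

    def test_library_spans_camera_channel_space(self, camera):
        lib = cc.make_spectrum_library(200, seed=7)
        resp = normalized_catches(lib, camera.sensitivity_matrix())
        assert np.linalg.matrix_rank(resp, tol=1e-8) == 4


class TestRendering:
    def test_flat_reflectance_gives_flat_catches(self, camera):
        flat = np.full((1, WAVELENGTHS.size), 0.948)
        catches = normalized_catches(flat, camera.sensitivity_matrix())
        np.testing.assert_allclose(catches, 0.948, atol=1e-12)

    def test_linearity_in_reflectance(self, camera):
        lib = cc.make_spectrum_library(10, seed=4) * 0.5
        S = camera.sensitivity_matrix()
        np.testing.assert_allclose(normalized_catches(2 * lib, S),
                                   2 * normalized_catches(lib, S), rtol=1e-12)

    def test_catches_match_trapezoid_oracle(self, camera, peafowl_vs):
        lib = cc.make_spectrum_library(25, seed=5)
        for sens_matrix in (camera.sensitivity_matrix(),
                            peafowl_vs.sensitivity_matrix()):
            got = normalized_catches(lib, sens_matrix)
            for i in range(lib.shape[0]):
                for c in range(sens_matrix.shape[0]):
                    assert got[i, c] == pytest.approx(
                        trapezoid_catch_oracle(lib[i], sens_matrix[c]),
                        abs=1e-10)

    def test_grid_mismatch_rejected(self, camera):
        with pytest.raises(ValueError, match="grid"):
            normalized_catches(np.ones((3, 40)), camera.sensitivity_matrix())

    def test_standard_patch_ratio(self, mudflat_scene, camera):
        img = cc.render_camera_image(mudflat_scene, camera)
        white = mudflat_scene.masks["standard_white"]
        black = mudflat_scene.masks["standard_black"]
        for ch in img.channels.values():
            assert ch[white].mean() / ch[black].mean() == pytest.approx(
                0.948 / 0.082, rel=1e-9)

    def test_true_cone_catches_deterministic(self, mudflat_scene, peafowl_vs):
        a = cc.render_true_cone_catches(mudflat_scene, peafowl_vs)
        b = cc.render_true_cone_catches(mudflat_scene, peafowl_vs)
        for name in a.channels:
            np.testing.assert_array_equal(a.channels[name], b.channels[name])


class TestBackgroundScenes:
    def test_seeded_determinism(self):
        p = cc.HabitatTextureParams.mudflat()
        a = cc.make_background_scene(p, size=(256, 256), seed=5)
        b = cc.make_background_scene(p, size=(256, 256), seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.spectra, b.spectra)

    def test_too_small_scene_rejected(self):
        with pytest.raises(ValueError):
            cc.make_background_scene(cc.HabitatTextureParams.mudflat(),
                                     size=(128, 128), seed=0)

    def test_masks_disjoint_and_standards_nonempty(self, rockpool_scene):
        s = rockpool_scene
        total = sum(m.astype(int) for m in s.masks.values())
        assert total.max() == 1
        assert s.masks["standard_white"].any()
        assert s.masks["standard_black"].any()

    def test_contrast_calibration_and_class_ordering(
            self, mudflat_scene, rockpool_scene, mudflat_luminance,
            rockpool_luminance):
        for scene, lum, target in (
                (mudflat_scene, mudflat_luminance, 0.08),
                (rockpool_scene, rockpool_luminance, 0.35)):
            v = lum[scene.usable()]
            contrast = v.std() / v.mean()
            assert abs(contrast - target) / target < 0.2
        mf = mudflat_luminance[mudflat_scene.usable()]
        rp = rockpool_luminance[rockpool_scene.usable()]
        assert rp.std() / rp.mean() > mf.std() / mf.mean()

    def test_class_separation_total_pattern_energy(self, luminance_sensitivity):
        """Rockpool scenes carry more granularity energy than mudflat scenes
        at every seed (class separation used downstream)."""
        from conftest import scene_luminance
        scales = [2.0, 4.0, 8.0, 16.0, 32.0, 64.0]
        totals = {"mudflat": [], "rockpool": []}
        for seed in range(10):
            for name, params in (("mudflat", cc.HabitatTextureParams.mudflat()),
                                 ("rockpool", cc.HabitatTextureParams.rockpool())):
                s = cc.make_background_scene(params, size=(256, 256), seed=seed)
                lum = scene_luminance(s, luminance_sensitivity)
                sp = cc.granularity_spectrum(lum, s.usable(), scales)
                totals[name].append(sp.total_energy())
        assert np.mean(totals["rockpool"]) > np.mean(totals["mudflat"])


class TestCrabTargets:
    def test_uniform_crab_has_constant_interior(self, uniform_crab):
        assert uniform_crab.blotch_mask().sum() == 0
        stack = uniform_crab.reflectance_stack()[uniform_crab.mask]
        assert np.ptp(stack, axis=0).max() == 0

    def test_mask_connected_and_hole_free(self, disruptive_crab):
        from scipy import ndimage
        mask = disruptive_crab.mask
        assert ndimage.label(mask, structure=np.ones((3, 3)))[1] == 1
        filled = ndimage.binary_fill_holes(mask)
        np.testing.assert_array_equal(filled, mask)

    def test_edge_bias_contract(self):
        from scipy import ndimage
        phen = cc.CrabPhenotype(style="disruptive",
                                base_spectrum=synthetic.sand_spectrum(),
                                blotch_count=10, blotch_contrast=0.7,
                                edge_bias=0.8, carapace_width=8.0)
        crab = cc.make_crab(phen, px_per_mm=10.0, seed=3)
        dist = ndimage.distance_transform_edt(crab.mask)
        band = crab.mask & (dist <= 0.25 * dist.max())
        blotch = crab.blotch_mask()
        assert (blotch & band).sum() / blotch.sum() >= 0.8

    def test_disruptive_blotches_touch_outline_band(self, uniform_crab,
                                                    disruptive_crab):
        from scipy import ndimage
        dist = ndimage.distance_transform_edt(disruptive_crab.mask)
        outline_band = disruptive_crab.mask & (dist <= 2)
        assert (disruptive_crab.blotch_mask() & outline_band).sum() > 0
        assert uniform_crab.blotch_mask().sum() == 0

    def test_too_small_crab_rejected(self):
        phen = cc.CrabPhenotype(style="uniform",
                                base_spectrum=synthetic.mud_spectrum(),
                                carapace_width=1.0)
        with pytest.raises(ValueError):
            cc.make_crab(phen, px_per_mm=10.0, seed=0)

    def test_juvenile_size_cap(self):
        with pytest.raises(ValueError):
            cc.CrabPhenotype(style="uniform",
                             base_spectrum=synthetic.mud_spectrum(),
                             carapace_width=15.0)

    def test_uniform_style_forbids_blotches(self):
        with pytest.raises(ValueError):
            cc.CrabPhenotype(style="uniform",
                             base_spectrum=synthetic.mud_spectrum(),
                             blotch_count=3, carapace_width=8.0)
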