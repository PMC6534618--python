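"""Outline tracing, Gabor edge energy, GabRat and random placement."""

import numpy as np
import pytest

from crabcamo.disruption import (Placement, extract_outline,
                                 gabor_energy, gabrat, local_tangents,
                                 mean_gabrat, sample_placements)


def square_mask(side=10, pad=4):
    m = np.zeros((side + 2 * pad, side + 2 * pad), dtype=bool)
    m[pad:pad + side, pad:pad + side] = True
    return m


def disc_mask(radius=30, pad=10):
    n = 2 * (radius + pad)
    yy, xx = np.mgrid[:n, :n]
    return (yy - n / 2 + 0.5) ** 2 + (xx - n / 2 + 0.5) ** 2 <= radius ** 2


class TestOutline:
    def test_square_perimeter_count(self):
        assert len(extract_outline(square_mask(10))) == 36

    def test_traversal_closed_and_adjacent(self):
        o = extract_outline(disc_mask(20))
        steps = np.diff(np.vstack([o, o[:1]]), axis=0)
        assert np.abs(steps).max() == 1

    def test_disc_boundary_length_near_circumference(self):
        o = extract_outline(disc_mask(30))
        steps = np.diff(np.vstack([o, o[:1]]), axis=0)
        length = np.hypot(steps[:, 0], steps[:, 1]).sum()
        assert abs(length - np.pi * 60) / (np.pi * 60) < 0.05

    def test_empty_and_fragmented_masks_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_outline(np.zeros((5, 5), bool))
        two = np.zeros((10, 10), bool)
        two[1:3, 1:3] = True
        two[6:8, 6:8] = True
        with pytest.raises(ValueError, match="components"):
            extract_outline(two)


class TestTangents:
    def test_square_edges_axis_aligned(self):
        o = extract_outline(square_mask(12))
        t = local_tangents(o, window=7)
        # interior edge pixels (away from corners) are exactly 0 or pi/2
        counts = sum(1 for a in t
                     if min(a, abs(a - np.pi / 2), np.pi - a) < 1e-9)
        assert counts >= 4 * (12 - 7)

    def test_diagonal_edge(self):
        n = 40
        yy, xx = np.mgrid[:n, :n]
        tri = (yy + xx) >= n  # 45-degree hypotenuse
        o = extract_outline(tri)
        t = local_tangents(o, window=7)
        # hypotenuse-interior samples, away from the corners
        on_diag = (o.sum(axis=1) == n) & (o[:, 1] > 8) & (o[:, 1] < n - 8)
        assert on_diag.sum() > n // 2
        assert np.all(np.abs(t[on_diag] - 3 * np.pi / 4) < 0.05)

    def test_rotation_equivariance(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[20:40, 12:50] = True
        yy, xx = np.mgrid[:60, :60]
        mask |= (yy - 28) ** 2 + (xx - 18) ** 2 <= 12 ** 2
        o = extract_outline(mask)
        t = local_tangents(o, window=7)
        o90 = extract_outline(np.rot90(mask))
        t90 = local_tangents(o90, window=7)
        # same multiset of angles, shifted by 90 degrees
        a = np.sort(np.mod(t + np.pi / 2, np.pi).round(9))
        b = np.sort(t90.round(9))
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_window_validation(self):
        o = extract_outline(square_mask(10))
        with pytest.raises(ValueError):
            local_tangents(o, window=4)
        with pytest.raises(ValueError):
            local_tangents(o[:3], window=7)


class TestGaborEnergy:
    def test_constant_image_zero(self):
        img = np.full((40, 40), 7.0)
        assert gabor_energy(img, (20, 20), 0.3) == pytest.approx(0.0, abs=1e-9)

    def test_offset_invariance(self):
        rng = np.random.default_rng(0)
        img = rng.standard_normal((40, 40))
        e1 = gabor_energy(img, (20, 20), 1.1)
        e2 = gabor_energy(img + 5.0, (20, 20), 1.1)
        assert e1 == pytest.approx(e2, abs=1e-9)

    @pytest.mark.parametrize("theta,edge", [
        (0.0, lambda yy, xx, n: yy > n // 2),            # horizontal edge
        (np.pi / 2, lambda yy, xx, n: xx > n // 2),      # vertical edge
        (3 * np.pi / 4, lambda yy, xx, n: yy + xx > n),  # diagonal edge
    ])
    def test_step_edge_maximises_at_its_orientation(self, theta, edge):
        """Across a dense orientation bank, energy peaks at the edge's own
        orientation."""
        n = 64
        yy, xx = np.mgrid[:n, :n]
        img = edge(yy, xx, n) * 1.0
        bank = np.linspace(0, np.pi, 37)
        energies = [gabor_energy(img, (n // 2, n // 2), a) for a in bank]
        best = bank[int(np.argmax(energies))]
        delta = min(abs(best - theta), np.pi - abs(best - theta))
        assert delta < np.pi / 18


class TestGabRat:
    def test_uniform_disc_on_uniform_field(self):
        mask = disc_mask(30)
        img = np.zeros(mask.shape)
        img[mask] = 1.0
        g = gabrat(img, mask)
        assert 0.0 <= g < 0.1

    def test_background_continuation_exceeds_half(self):
        """A target whose oriented texture continues the background across
        most of its outline is dominated by false edges."""
        H = W = 200
        stripes = np.sin(2 * np.pi * np.arange(H) / 10.0)[:, None] * np.ones((1, W))
        rect = np.zeros((H, W), bool)
        rect[40:160, 90:110] = True  # tall & thin: mostly vertical outline
        assert gabrat(stripes, rect) > 0.5

    def test_bounded_and_offset_invariant(self, disruptive_crab,
                                          luminance_sensitivity):
        from conftest import crab_luminance
        lum = crab_luminance(disruptive_crab, luminance_sensitivity)
        g1 = gabrat(lum, disruptive_crab.mask)
        g2 = gabrat(lum + 0.7, disruptive_crab.mask)
        assert 0.0 <= g1 <= 1.0
        assert g1 == pytest.approx(g2, abs=1e-9)

    def test_rotation_equivariance(self, disruptive_crab,
                                   luminance_sensitivity):
        from conftest import crab_luminance
        lum = crab_luminance(disruptive_crab, luminance_sensitivity)
        g = gabrat(lum, disruptive_crab.mask)
        g90 = gabrat(np.rot90(lum), np.rot90(disruptive_crab.mask))
        assert g == pytest.approx(g90, abs=1e-6)

    def test_featureless_scene_warns_and_returns_zero(self):
        mask = disc_mask(20)
        with pytest.warns(UserWarning, match="featureless"):
            assert gabrat(np.zeros(mask.shape), mask) == 0.0


class TestPlacements:
    def test_single_placement_in_bounds(self):
        mask = disc_mask(10)
        p = sample_placements((256, 256), mask, 1, seed=0)
        assert len(p) == 1
        oy, ox = p[0].offset
        assert 0 <= oy <= 256 - mask.shape[0]
        assert 0 <= ox <= 256 - mask.shape[1]

    def test_fifty_disjoint_on_large_background(self):
        """50 placements of a 60 px crab on 1024² are pairwise disjoint and
        avoid the exclusion zone (verified by mask arithmetic)."""
        mask = disc_mask(30)
        excl = np.zeros((1024, 1024), bool)
        excl[:120, :250] = True
        ps = sample_placements((1024, 1024), mask, 50, exclusion=excl, seed=3)
        assert len(ps) == 50
        occupancy = np.zeros((1024, 1024), dtype=int)
        h, w = mask.shape
        for p in ps:
            oy, ox = p.offset
            occupancy[oy:oy + h, ox:ox + w] += mask
        assert occupancy.max() == 1
        assert (occupancy.astype(bool) & excl).sum() == 0

    def test_seeded_determinism(self):
        mask = disc_mask(10)
        a = sample_placements((300, 300), mask, 10, seed=9)
        b = sample_placements((300, 300), mask, 10, seed=9)
        assert [p.offset for p in a] == [p.offset for p in b]

    def test_overcrowded_background_reports_achieved_count(self):
        mask = disc_mask(30)
        with pytest.raises(RuntimeError, match="placed only"):
            sample_placements((90, 90), mask, 3, seed=0, max_attempts=200)

    def test_target_larger_than_background_rejected(self):
        with pytest.raises(ValueError):
            sample_placements((50, 50), disc_mask(30), 1, seed=0)


class TestMeanGabRat:
    def test_single_placement_equals_direct_gabrat(
            self, uniform_crab, mudflat_luminance, mudflat_scene,
            luminance_sensitivity):
        from conftest import crab_luminance
        lum = crab_luminance(uniform_crab, luminance_sensitivity)
        excl = mudflat_scene.placement_exclusion()
        m, values = mean_gabrat(lum, uniform_crab.mask,
                                mudflat_luminance.copy(), n=1,
                                exclusion=excl, seed=4)
        assert m == values[0]
        # recompute by hand at the same placement
        p = sample_placements(mudflat_luminance.shape, uniform_crab.mask, 1,
                              exclusion=excl, seed=4)[0]
        comp = mudflat_luminance.copy()
        oy, ox = p.offset
        h, w = uniform_crab.mask.shape
        win = comp[oy:oy + h, ox:ox + w]
        win[uniform_crab.mask] = lum[uniform_crab.mask]
        full_mask = np.zeros(comp.shape, bool)
        full_mask[oy:oy + h, ox:ox + w] = uniform_crab.mask
        assert m == pytest.approx(gabrat(comp, full_mask), abs=1e-12)

    def test_reproducible_and_background_restored(
            self, uniform_crab, mudflat_luminance, mudflat_scene,
            luminance_sensitivity):
        from conftest import crab_luminance
        lum = crab_luminance(uniform_crab, luminance_sensitivity)
        bg = mudflat_luminance.copy()
        excl = mudflat_scene.placement_exclusion()
        m1, _ = mean_gabrat(lum, uniform_crab.mask, bg, n=4,
                            exclusion=excl, seed=11)
        np.testing.assert_array_equal(bg, mudflat_luminance)
        m2, _ = mean_gabrat(lum, uniform_crab.mask, bg, n=4,
                            exclusion=excl, seed=11)
        assert m1 == m2
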