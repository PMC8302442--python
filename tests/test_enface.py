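"""Plane fitting, oblique projection, line profiles, depletion statistic."""

import numpy as np
import pytest

from synapse4d.enface import (EnFaceMap, Plane, depletion_fraction,
                              enface_projection, fit_synapse_plane,
                              line_profile)
from synapse4d.movie import Movie
from synapse4d.params import FIXED_DEFAULTS
from synapse4d.render import render_conjugate_stack
from synapse4d.segmentation import extract_synapse_surface, segment_cells

VOX = (0.2, 0.2, 0.2)


def _plane_points(normal, n=200, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    normal = np.asarray(normal) / np.linalg.norm(normal)
    seed_v = np.array([1.0, 0.0, 0.0])
    if abs(seed_v @ normal) > 0.9:
        seed_v = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, seed_v)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    a = rng.uniform(-3, 3, n)
    b = rng.uniform(-3, 3, n)
    pts = (np.array([5.0, 5.0, 5.0]) + a[:, None] * u + b[:, None] * v)
    if jitter:
        pts += rng.uniform(-jitter, jitter, (n, 3))
    return pts


class TestFitPlane:
    def test_axis_aligned_contact(self):
        pts = _plane_points([0, 0, 1])
        plane = fit_synapse_plane(pts)
        assert abs(plane.normal @ np.array([0, 0, 1.0])) > 0.9999

    def test_tilted_plane_within_2_degrees(self):
        n_true = np.array([0.0, np.sin(np.deg2rad(30)), np.cos(np.deg2rad(30))])
        plane = fit_synapse_plane(_plane_points(n_true))
        ang = np.degrees(np.arccos(min(abs(plane.normal @ n_true), 1.0)))
        assert ang < 2.0

    def test_jittered_plane_within_5_degrees(self):
        n_true = np.array([0.3, 0.3, 0.906])
        n_true /= np.linalg.norm(n_true)
        plane = fit_synapse_plane(_plane_points(n_true, jitter=0.2, seed=3))
        ang = np.degrees(np.arccos(min(abs(plane.normal @ n_true), 1.0)))
        assert ang < 5.0

    def test_collinear_surface_raises(self):
        pts = np.stack([np.zeros(10), np.zeros(10), np.arange(10.0)], axis=1)
        with pytest.raises(ValueError, match="degenerate|collinear"):
            fit_synapse_plane(pts)

    def test_orientation_follows_cell_centroids(self):
        pts = _plane_points([0, 0, 1])
        plane = fit_synapse_plane(pts, ctl_centroid_um=[5, 5, 2],
                                  target_centroid_um=[5, 5, 8])
        assert plane.normal[2] > 0


class TestProjection:
    def _stack(self, fill):
        return np.asarray(fill, dtype=np.float32)

    def test_uniform_volume_uniform_map(self):
        stack = np.full((1, 20, 30, 30), 7.0, dtype=np.float32)
        plane = Plane(np.array([2.0, 3.0, 3.0]), np.array([1.0, 0.0, 0.0]))
        m = enface_projection(stack, plane, VOX, ("a",), half_extent_um=1.5)
        assert np.allclose(m.channel("a"), 7.0)

    def test_axis_aligned_equals_substack_projection(self):
        # intensity is a pure function of y, so the direct sub-stack max
        # projection is that same ramp; the axis-aligned en-face map must
        # reproduce it exactly (up to in-plane axis orientation)
        shape = (1, 24, 20, 20)
        yy = np.indices(shape[1:])[1].astype(np.float32) * VOX[1]
        stack = yy[None]
        z0, y0 = 12, 10
        plane = Plane(np.array([z0 * VOX[0], y0 * VOX[1], 2.0]),
                      np.array([1.0, 0.0, 0.0]))
        h = 1.0
        m = enface_projection(stack, plane, VOX, ("a",),
                              slab_thickness_um=1.2, half_extent_um=h)
        direct = stack[0, z0 - 3:z0 + 4].max(axis=0)      # = y ramp
        in_window = np.abs(np.arange(20) * VOX[1] - y0 * VOX[1]) <= h + 1e-9
        want = direct[in_window, 0]
        img = m.channel("a")
        # every map row/column set equals the ramp values inside the window
        got = np.sort(np.unique(np.round(img, 5)))
        expect = np.sort(np.unique(np.round(want, 5)))
        assert np.allclose(got, expect, atol=1e-4)

    def test_ring_pattern_radii(self):
        zz, yy, xx = np.indices((30, 40, 40)).astype(float)
        rho = np.sqrt(((yy - 20) * 0.2) ** 2 + ((xx - 20) * 0.2) ** 2)
        ring = ((rho > 1.0) & (rho < 2.0) & (np.abs((zz - 15) * 0.2) < 0.3))
        stack = (100.0 * ring)[None].astype(np.float32)
        plane = Plane(np.array([3.0, 4.0, 4.0]), np.array([1.0, 0.0, 0.0]))
        m = enface_projection(stack, plane, VOX, ("a",), half_extent_um=3.0)
        img = m.channel("a")
        c = img.shape[0] // 2
        profile = img[c]
        bright = np.flatnonzero(profile > 50)
        r_inner = np.abs(bright - c).min() * m.pixel_size_um
        r_outer = np.abs(bright - c).max() * m.pixel_size_um
        assert r_inner == pytest.approx(1.0, abs=0.25)
        assert r_outer == pytest.approx(2.0, abs=0.25)

    def test_partial_slab_warns(self):
        stack = np.full((1, 10, 10, 10), 1.0, dtype=np.float32)
        plane = Plane(np.array([0.2, 1.0, 1.0]), np.array([1.0, 0.0, 0.0]))
        with pytest.warns(UserWarning, match="partially outside"):
            enface_projection(stack, plane, VOX, ("a",), half_extent_um=0.6)


class TestLineProfile:
    def test_constant_image(self):
        img = np.full((20, 20), 3.0)
        _, prof = line_profile(img, (10, 2), (10, 17))
        assert np.allclose(prof, 3.0)

    def test_step_edge_location(self):
        img = np.zeros((20, 30))
        img[:, 15:] = 10.0
        d, prof = line_profile(img, (10, 0), (10, 29))
        crossing = np.flatnonzero(prof > 5.0)[0]
        assert crossing == pytest.approx(15, abs=1)

    def test_annulus_two_peaks_with_trough(self):
        yy, xx = np.indices((41, 41)).astype(float)
        rho = np.sqrt((yy - 20) ** 2 + (xx - 20) ** 2)
        img = ((rho > 8) & (rho < 14)) * 100.0
        _, prof = line_profile(img, (20, 0), (20, 40))
        centre = prof[18:23].max()
        peaks = max(prof[:18].max(), prof[23:].max())
        assert peaks > 50
        assert centre < 10

    def test_endpoints_validated(self):
        with pytest.raises(ValueError):
            line_profile(np.zeros((10, 10)), (5, 5), (5, 20))


def _binary_map(img, px=1.0):
    return EnFaceMap(maps={"m": img.astype(float)},
                     plane=Plane(np.zeros(3), np.array([1.0, 0, 0])),
                     pixel_size_um=px, slab_thickness_um=3.0,
                     basis_um=np.eye(3)[1:])


class TestDepletionFormula:
    def test_exact_on_binary_fixture(self):
        # footprint 100 px with a 25 px internal hole -> exactly 25%
        img = np.zeros((20, 20))
        img[5:15, 5:15] = 1.0        # 100 px
        img[7:12, 7:12] = 0.0        # 25 px hole
        res = depletion_fraction(_binary_map(img), "m",
                                 threshold_method="fixed",
                                 threshold_value=0.5)
        assert res.percent_depleted == pytest.approx(25.0)
        assert res.synapse_footprint_area_um2 == pytest.approx(100.0)

    def test_solid_disk_zero_percent(self):
        img = np.zeros((20, 20))
        img[5:15, 5:15] = 1.0
        res = depletion_fraction(_binary_map(img), "m",
                                 threshold_method="fixed",
                                 threshold_value=0.5)
        assert res.percent_depleted == 0.0

    def test_debris_outside_footprint_ignored(self):
        img = np.zeros((30, 30))
        img[5:15, 5:15] = 1.0
        img[7:12, 7:12] = 0.0
        img[25:27, 25:27] = 1.0      # debris
        res = depletion_fraction(_binary_map(img), "m",
                                 threshold_method="fixed",
                                 threshold_value=0.5)
        assert res.percent_depleted == pytest.approx(25.0)

    def test_empty_footprint_raises(self):
        with pytest.raises(ValueError, match="footprint|synapse"):
            depletion_fraction(_binary_map(np.zeros((10, 10))), "m",
                               threshold_method="fixed", threshold_value=0.5)

    def test_otsu_route_scale_invariant(self):
        img = np.zeros((20, 20))
        img[5:15, 5:15] = 1.0
        img[7:12, 7:12] = 0.2
        a = depletion_fraction(_binary_map(img), "m",
                               threshold_method="otsu")
        b = depletion_fraction(_binary_map(img * 37.0), "m",
                               threshold_method="otsu")
        assert a.percent_depleted == pytest.approx(b.percent_depleted)


def _end_to_end(frac, seed):
    stack, truth = render_conjugate_stack(frac, FIXED_DEFAULTS, rng_seed=seed)
    mv = Movie(stack[None], FIXED_DEFAULTS.with_(n_frames=1))
    ctl = segment_cells(mv, "actin", min_volume_um3=4.0)
    tgt = segment_cells(mv, "target", min_volume_um3=4.0)
    surf = extract_synapse_surface(ctl.labels[0] > 0, tgt.labels[0] > 0,
                                   FIXED_DEFAULTS.voxel_size_zyx)
    plane = fit_synapse_plane(surf.coords_um, np.zeros(3),
                              np.asarray(truth.plane_normal) * 10)
    emap = enface_projection(stack, plane, FIXED_DEFAULTS.voxel_size_zyx,
                             FIXED_DEFAULTS.channel_names, half_extent_um=4.5)
    return depletion_fraction(emap, "actin").percent_depleted


class TestEndToEnd:
    def test_quarter_depletion_recovered(self):
        assert _end_to_end(0.25, 1) == pytest.approx(25.0, abs=5.0)

    def test_forty_percent_recovered(self):
        assert _end_to_end(0.40, 3) == pytest.approx(40.0, abs=5.0)

    def test_zero_depletion(self):
        assert _end_to_end(0.0, 2) < 2.0

    def test_rotation_invariance(self):
        # same latent fraction under different random plane orientations
        vals = [_end_to_end(0.40, s) for s in (3, 13, 23)]
        assert max(vals) - min(vals) <= 4.0

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            render_conjugate_stack(1.3, FIXED_DEFAULTS, rng_seed=1)
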