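"""Segmentation, midline, tip and surface-band geometry against analytic
and brute-force oracles."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree

import rootph as rp
from rootph.errors import (
    DegenerateTopologyError,
    NoRootFoundError,
    ShortRootError,
    StainingFailureError,
)
from rootph.geometry import compute_geometry, detect_tip, extract_midline


def _two_level(shape=(300, 120), rect=(slice(40, 240), slice(50, 70)),
               bright=1000.0, dark=10.0):
    img = np.full(shape, bright)
    img[rect] = dark
    return np.stack([img, img])


def iou(a, b):
    return (a & b).sum() / (a | b).sum()


class TestSegmentation:
    def test_two_level_rectangle_exact(self):
        frame = _two_level()
        mask = rp.segment_root(frame)
        truth = np.zeros(frame.shape[1:], bool)
        truth[40:240, 50:70] = True
        assert iou(mask, truth) >= 0.99

    def test_phantom_mask_recovery(self, halo_phantom, default_config):
        _, stack, truth = halo_phantom
        mask = rp.segment_root(stack.frame(0), default_config)
        assert iou(mask, truth.masks[0]) >= 0.95

    def test_uniform_image_raises(self):
        with pytest.raises(NoRootFoundError):
            rp.segment_root(np.full((2, 100, 100), 500.0))

    def test_mostly_dark_image_is_staining_failure(self):
        img = np.full((100, 100), 5.0)
        img[:5] = 1000.0
        with pytest.raises(StainingFailureError):
            rp.segment_root(np.stack([img, img]), rp.RunConfig(flatfield_sigma_px=0))


class TestMidline:
    def test_straight_rectangle_length(self):
        mask = np.zeros((420, 120), bool)
        mask[0:400, 50:70] = True
        geo = compute_geometry(mask, pixel_size_um=0.65)
        assert geo.length_um == pytest.approx(400 * 0.65, rel=0.05)

    def test_quarter_circle_arc_length(self):
        yy, xx = np.mgrid[0:260, 0:260]
        mask = np.abs(np.hypot(yy, xx) - 200) <= 10
        geo = compute_geometry(mask, pixel_size_um=1.0)
        assert geo.length_um == pytest.approx(np.pi / 2 * 200, rel=0.05)

    def test_disc_is_degenerate(self):
        yy, xx = np.mgrid[0:100, 0:100]
        disc = (yy - 50) ** 2 + (xx - 50) ** 2 <= 40 ** 2
        with pytest.raises(DegenerateTopologyError):
            extract_midline(disc)

    def test_arc_length_strictly_increasing_from_tip(self, halo_phantom):
        _, stack, _ = halo_phantom
        mask = rp.segment_root(stack.frame(0))
        geo = compute_geometry(mask, stack.pixel_size_um)
        assert geo.arc_s_um[0] == 0.0
        assert (np.diff(geo.arc_s_um) > 0).all()
        # the tip sits on or within a pixel of the mask
        iy, ix = int(round(geo.tip[0])), int(round(geo.tip[1]))
        neighborhood = mask[max(iy - 1, 0):iy + 2, max(ix - 1, 0):ix + 2]
        assert neighborhood.any()


class TestTip:
    def test_vertical_root_tip_and_tangent(self):
        mask = np.zeros((300, 120), bool)
        mask[0:250, 50:70] = True
        geo = compute_geometry(mask, 1.0)
        assert geo.tip[0] > 200  # bottom endpoint
        assert geo.tip_tangent @ np.array([1.0, 0.0]) > 0.99  # points down

    def test_rotated_phantom_angle(self):
        spec = rp.PhantomSpec(initial_angle_deg=30.0, image_shape=(640, 760), seed=2)
        stack, _ = rp.make_phantom(spec)
        mask = rp.segment_root(stack.frame(0))
        geo = compute_geometry(mask, 1.0)
        ang = np.degrees(np.arccos(np.clip(geo.tip_tangent @ np.array([1.0, 0.0]), -1, 1)))
        assert ang == pytest.approx(30.0, abs=2.0)

    def test_floating_mask_uses_gravity_rule(self):
        # both endpoints interior: the deeper endpoint is the tip
        mask = np.zeros((300, 120), bool)
        mask[50:250, 50:70] = True
        geo = compute_geometry(mask, 1.0)
        assert geo.tip[0] > 200

    def test_short_midline_raises(self):
        midline = np.column_stack([np.arange(10.0), np.full(10, 5.0)])
        with pytest.raises(ShortRootError):
            detect_tip(midline, np.ones((20, 20), bool), np.array([1.0, 0.0]))


class TestSurfaceBand:
    def test_disc_band_equals_brute_force(self):
        yy, xx = np.mgrid[0:128, 0:128]
        mask = (yy - 64) ** 2 + (xx - 64) ** 2 <= 30 ** 2
        dist = ndimage.distance_transform_edt(~mask)
        sel = (dist >= 10) & (dist <= 25) & ~mask
        got = set(map(tuple, np.column_stack(np.nonzero(sel))))
        mpts = np.column_stack(np.nonzero(mask))
        opts = np.column_stack(np.nonzero(~mask))
        d, _ = cKDTree(mpts).query(opts)
        want = set(map(tuple, opts[(d >= 10) & (d <= 25)]))
        assert got == want

    def test_disc_band_pixel_count_matches_annulus_area(self):
        yy, xx = np.mgrid[0:256, 0:256]
        mask = (yy - 128) ** 2 + (xx - 128) ** 2 <= 50 ** 2
        dist = ndimage.distance_transform_edt(~mask)
        count = ((dist >= 10) & (dist <= 25)).sum()
        expected = np.pi * (75 ** 2 - 60 ** 2)
        assert count == pytest.approx(expected, rel=0.03)

    def test_band_pixels_respect_radial_bounds(self, halo_phantom, default_config):
        _, stack, _ = halo_phantom
        mask = rp.segment_root(stack.frame(0), default_config)
        geo = compute_geometry(mask, stack.pixel_size_um)
        band = rp.extract_surface_band(geo, stack.frame(0), default_config)
        assert band.dist_px.min() >= default_config.band_min_px
        assert band.dist_px.max() <= default_config.band_max_px
        assert not mask[band.yx[:, 0], band.yx[:, 1]].any()
        assert (band.s_um >= 0).all()

    def test_band_geometry_independent_of_intensities(self, halo_phantom, default_config):
        _, stack, _ = halo_phantom
        mask = rp.segment_root(stack.frame(0), default_config)
        geo = compute_geometry(mask, stack.pixel_size_um)
        b1 = rp.extract_surface_band(geo, stack.frame(0), default_config)
        b2 = rp.extract_surface_band(geo, stack.frame(0) * 3.7 + 1.0, default_config)
        assert np.array_equal(b1.yx, b2.yx)
        assert np.array_equal(b1.s_um, b2.s_um)
        assert np.array_equal(b1.side, b2.side)

    def test_sides_balanced_for_straight_phantom(self, halo_phantom, default_config):
        _, stack, _ = halo_phantom
        mask = rp.segment_root(stack.frame(0), default_config)
        geo = compute_geometry(mask, stack.pixel_size_um)
        band = rp.extract_surface_band(geo, stack.frame(0), default_config)
        n_left = (band.side == 1).sum()
        n_right = (band.side == -1).sum()
        assert abs(n_left - n_right) / max(n_left, n_right) < 0.10

    def test_rotation_equivariance_of_profile(self, halo_phantom, default_config, run_profile):
        """Rotating the image by 90 deg leaves the longitudinal profile
        unchanged within discretization."""
        profile_from_stack = run_profile
        _, stack, _ = halo_phantom
        rot = rp.ChannelStack(
            data=np.rot90(stack.data, k=1, axes=(2, 3)).copy(),
            pixel_size_um=stack.pixel_size_um,
            gravity_vector=np.array([0.0, -1.0]),  # co-rotated gravity
        )
        p0 = profile_from_stack(stack, default_config)
        p1 = profile_from_stack(rot, default_config)
        v0 = dict(zip(p0.positions(), p0.values()))
        v1 = dict(zip(p1.positions(), p1.values()))
        common = sorted(set(v0) & set(v1))
        assert len(common) > 20
        diffs = [abs(v0[p] - v1[p]) / v0[p] for p in common]
        assert np.median(diffs) < 0.01
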