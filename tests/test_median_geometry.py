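"""Centroid, radial ray fan, weighted medians, median line and length."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import c8morph as c8
from c8morph.median_geometry import Centroid, MedianLine, RayFan

from conftest import STD_LENGTH


def brute_weighted_median(radii, weights):
    """Independent oracle: walk the sorted cumulative weights."""
    order = np.argsort(radii, kind="stable")
    total = float(np.sum(weights))
    acc = 0.0
    for i in order:
        acc += weights[i]
        if acc >= total / 2:
            return radii[i]
    return radii[order[-1]]


def synthetic_fan(radii, prob_rows, angles=None, centroid=(0.0, 0.0)):
    probs = np.atleast_2d(np.asarray(prob_rows, dtype=float))
    if angles is None:
        angles = np.arange(probs.shape[0], dtype=float)
    return RayFan(slc=None, masked_data=None, centroid=Centroid(*centroid),
                  angles_deg=np.asarray(angles, dtype=float),
                  radii_mm=np.asarray(radii, dtype=float),
                  probabilities=probs, wm_threshold=0.5)


class TestCentroid:
    def test_symmetric_arch_centered(self, std_cluster):
        c = c8.compute_centroid(std_cluster)
        assert c.y_mm == pytest.approx(0.0, abs=0.5)
        # inferior splenium extent = arc-end level z = 15 (within a voxel)
        assert c.z_mm == pytest.approx(15.0, abs=1.0)

    def test_translation_equivariance(self):
        a = c8.PhantomSpec(center_mni=(0.0, 15.0), blur_sigma_mm=0.5)
        b = c8.PhantomSpec(center_mni=(10.0, 15.0), blur_sigma_mm=0.5)
        cents = []
        for spec in (a, b):
            vol, _ = c8.make_arch_phantom(spec)
            slc = c8.extract_parasagittal_slices(vol, [0.0])[0]
            cents.append(c8.compute_centroid(c8.extract_callosum(slc)))
        assert cents[1].y_mm - cents[0].y_mm == pytest.approx(10.0, abs=1e-9)
        assert cents[1].z_mm == pytest.approx(cents[0].z_mm, abs=1e-9)

    def test_splenium_dip_sets_z(self, std_slice):
        # add a dip 3 mm below the arc end within the posterior 20%
        cluster = c8.extract_callosum(std_slice)
        mask = cluster.mask.copy()
        iy = np.searchsorted(std_slice.y_axis, -10.0)
        iz0 = np.searchsorted(std_slice.z_axis, 15.0)
        mask[iy, iz0 - 3:iz0] = True  # dip to z = 12
        from c8morph.extraction import CallosalCluster
        dipped = CallosalCluster(mask=mask, slice_ref=std_slice, wm_threshold=0.5)
        c = c8.compute_centroid(dipped)
        assert c.z_mm == pytest.approx(std_slice.z_axis[iz0 - 3], abs=1e-9)


class TestRayFan:
    def test_ray_count_at_default_step(self, std_slice, std_cluster):
        fan = c8.cast_radial_rays(std_slice, std_cluster,
                                  c8.compute_centroid(std_cluster))
        assert len(fan) == int(np.ceil(360 / 1.65))  # 219

    def test_half_annulus_intersection_span(self, std_slice, std_cluster):
        fan = c8.cast_radial_rays(std_slice, std_cluster,
                                  c8.compute_centroid(std_cluster))
        n_hit = int(fan.intersects.sum())
        # about 180 deg of arch plus tip wedges; the span seen from the
        # centroid (one voxel above the arc-end level) is slightly wider
        assert 175.0 < n_hit * fan.step_deg < 200.0

    def test_full_annulus_all_rays_intersect(self):
        spec = c8.PhantomSpec(center_mni=(0.0, 15.0), angular_span_deg=(0, 360),
                              blur_sigma_mm=0.5)
        vol, _ = c8.make_arch_phantom(spec)
        slc = c8.extract_parasagittal_slices(vol, [0.0])[0]
        # grow without branch pruning: pruning would correctly erase the
        # ring's inferior half (two supra runs per mid-body column)
        box = c8.BoundingBox(y_range_mm=(-55, 50), z_range_mm=(-5, 40))
        seeds = c8.find_seeds(slc, box, 0.5)
        cluster = c8.select_callosal_cluster(c8.grow_clusters(slc, seeds, 0.5))
        cen = Centroid(0.0, 15.0)  # geometric center of the closed annulus
        fan = c8.cast_radial_rays(slc, cluster, cen)
        assert fan.intersects.all()
        with pytest.raises(ValueError, match="tips"):
            c8.build_median_line(fan, cluster)

    def test_centroid_outside_grid(self, std_slice, std_cluster):
        with pytest.raises(ValueError, match="centroid"):
            c8.cast_radial_rays(std_slice, std_cluster, Centroid(500.0, 0.0))


class TestWeightedMedian:
    def test_uniform_band_median_at_center(self):
        radii = np.arange(0.25, 20, 0.25)
        probs = ((radii >= 10) & (radii <= 14)).astype(float)
        fan = synthetic_fan(radii, [probs], angles=[0.0])
        y, z = c8.weighted_median_point(fan, 0.0, wedge_deg=1.0)
        assert np.hypot(y, z) == pytest.approx(12.0, abs=0.25)

    def test_probability_squared_weighting(self):
        # samples at radii (10, 11, 12), probabilities (1, 1, 0.5):
        # squared weights (1, 1, 0.25) put the weighted median at 11
        fan = synthetic_fan([10.0, 11.0, 12.0], [[1.0, 1.0, 0.5]], angles=[0.0])
        y, _ = c8.weighted_median_point(fan, 0.0, wedge_deg=1.0)
        assert y == pytest.approx(11.0)

    def test_double_crossing_median_in_majority_run(self):
        # rostrum curl: runs at r in [5,6] and [12,14], equal probability;
        # the median lands in the run holding the cumulative-weight midpoint
        radii = np.arange(0.25, 20, 0.25)
        probs = (((radii >= 5) & (radii <= 6)) |
                 ((radii >= 12) & (radii <= 14))).astype(float)
        fan = synthetic_fan(radii, [probs], angles=[0.0])
        y, _ = c8.weighted_median_point(fan, 0.0, wedge_deg=1.0)
        assert 12.0 <= y <= 14.0
        assert y == pytest.approx(brute_weighted_median(radii, probs**2))

    def test_empty_wedge(self):
        fan = synthetic_fan([1.0, 2.0], [[0.0, 0.0]], angles=[0.0])
        with pytest.raises(ValueError):
            c8.weighted_median_point(fan, 90.0, wedge_deg=1.0)
        with pytest.raises(ValueError, match="mass"):
            c8.weighted_median_point(fan, 0.0, wedge_deg=1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0.5, 20.0), st.floats(0.01, 1.0)),
                    min_size=1, max_size=30))
    def test_matches_brute_force_on_random_rays(self, samples):
        radii = np.array([r for r, _ in samples])
        probs = np.array([p for _, p in samples])
        order = np.argsort(radii)
        fan = synthetic_fan(radii[order], [probs[order]], angles=[0.0])
        y, _ = c8.weighted_median_point(fan, 0.0, wedge_deg=1.0)
        assert y == pytest.approx(brute_weighted_median(radii, probs**2))


class TestMedianLine:
    def test_anchors_on_mid_radius_circle(self, std_line):
        r = np.linalg.norm(std_line.anchors - np.array([0.0, 15.0]), axis=1)
        rms = np.sqrt(np.mean((r - 10.0) ** 2))
        assert rms < 0.3

    def test_anchor_count_and_monotone_angles(self, std_line):
        assert std_line.n_anchors == 50
        d = np.diff(std_line.anchor_angles_deg)
        assert (d > 0).all() or (d < 0).all()

    def test_two_anchor_degenerate_line_is_tips(self, std_slice, std_cluster):
        cen = c8.compute_centroid(std_cluster)
        fan = c8.cast_radial_rays(std_slice, std_cluster, cen)
        line = c8.build_median_line(fan, std_cluster, n_anchors=2)
        assert line.n_anchors == 2
        # tips sit at the arc ends (z near the centroid level, y near +-10)
        assert np.all(np.abs(np.abs(line.anchors[:, 0]) - 10.0) < 1.5)

    def test_rotation_equivariance(self):
        base = c8.PhantomSpec(center_mni=(0.0, 15.0), blur_sigma_mm=0.5)
        rot = c8.PhantomSpec(center_mni=(0.0, 15.0), blur_sigma_mm=0.5,
                             angular_span_deg=(10.0, 190.0))
        lines = []
        for spec in (base, rot):
            vol, _ = c8.make_arch_phantom(spec)
            slc = c8.extract_parasagittal_slices(vol, [0.0])[0]
            cluster = c8.extract_callosum(slc, box=c8.BoundingBox(
                y_range_mm=(-55, 50), z_range_mm=(-5, 40)))
            cen = Centroid(0.0, 15.0)  # common origin isolates the rotation
            fan = c8.cast_radial_rays(slc, cluster, cen)
            lines.append(c8.build_median_line(fan, cluster))
        a = np.deg2rad(10.0)
        rotm = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        expected = (lines[0].anchors - [0, 15]) @ rotm.T + [0, 15]
        err = np.linalg.norm(lines[1].anchors - expected, axis=1)
        assert np.median(err) < 0.3


class TestMedianLength:
    def test_semicircle_length(self, std_line):
        mni, native = c8.median_length(std_line)
        assert mni == pytest.approx(STD_LENGTH, rel=0.03)
        assert native == mni

    def test_chord_sum_deficit_matches_closed_form(self):
        # 50 ideal anchors on a semicircle: chord sum / arc length equals
        # 2k*sin(pi/2k)/pi with k = 49 segments; deficit < 0.2%
        k = 49
        angles = np.linspace(0, np.pi, 50)
        anchors = 10.0 * np.column_stack([np.cos(angles), np.sin(angles)])
        line = MedianLine(anchors=anchors, anchor_angles_deg=np.rad2deg(angles),
                          tangents=np.zeros((50, 2)), centroid=Centroid(0, 0),
                          x_offset_mm=0.0)
        mni, _ = c8.median_length(line)
        expected_ratio = 2 * k * np.sin(np.pi / (2 * k)) / np.pi
        assert mni / (np.pi * 10.0) == pytest.approx(expected_ratio, abs=1e-9)
        assert 1 - mni / (np.pi * 10.0) < 0.002

    def test_pure_scaling_affine(self, std_line):
        native_affine = np.diag([1.1, 1.1, 1.1, 1.0])
        mni, native = c8.median_length(std_line, native_affine)
        assert native == pytest.approx(mni / 1.1, rel=1e-9)

    def test_identity_affine(self, std_line):
        mni, native = c8.median_length(std_line, np.eye(4))
        assert native == pytest.approx(mni, rel=1e-12)
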