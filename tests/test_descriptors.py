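"""The six descriptor families: distances, polygon scalars, Hu moments."""

import math

import numpy as np
import pytest

from rugometry.descriptors import (
    PAIR_ORDER,
    absolute_distances,
    compute_descriptors,
    hu_moments,
    landmark_polygon_descriptors,
    moment_invariants,
    relative_distances,
)
from rugometry.exceptions import DegenerateGeometryError
from rugometry.geometry import canonical_order
from rugometry.landmarks import LandmarkSet


def regular_hexagon(edge=1.0) -> LandmarkSet:
    ang = np.pi / 3 * np.arange(6)
    xy = edge * np.column_stack([np.cos(ang), np.sin(ang)])
    return LandmarkSet.from_array(xy, "photo", "hex")


def similarity(xy, k, theta, t):
    R = np.array([[math.cos(theta), -math.sin(theta)],
                  [math.sin(theta), math.cos(theta)]])
    return k * xy @ R.T + np.asarray(t)


class TestDistances:
    def test_pair_order_is_lexicographic(self):
        assert PAIR_ORDER[0] == (1, 2)
        assert PAIR_ORDER[1] == (1, 3)
        assert PAIR_ORDER[-1] == (5, 6)
        assert len(PAIR_ORDER) == 15

    def test_collinear_unit_spacing(self):
        lm = LandmarkSet.from_array(
            np.column_stack([np.arange(6.0), np.zeros(6)]), "photo", "s")
        d = absolute_distances(lm)
        assert d[PAIR_ORDER.index((1, 2))] == pytest.approx(1.0)
        assert d[PAIR_ORDER.index((1, 6))] == pytest.approx(5.0)

    def test_matches_brute_force_pair_loop(self, landmark_set):
        d = absolute_distances(landmark_set)
        xy = landmark_set.as_array()
        expected = []
        for i in range(6):
            for j in range(i + 1, 6):
                expected.append(math.dist(xy[i], xy[j]))
        assert np.allclose(d, expected)

    def test_relative_normalizes_by_max(self):
        abs_d = np.array([3.0, 4.0, 5.0] + [1.0] * 12)
        rel = relative_distances(abs_d)
        assert rel[:3] == pytest.approx([0.6, 0.8, 1.0])
        assert rel.max() == 1.0

    def test_relative_scale_invariance(self, landmark_set):
        d = absolute_distances(landmark_set)
        assert np.allclose(relative_distances(d), relative_distances(41.7 * d))

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            relative_distances(np.zeros(15))


class TestPolygonScalars:
    def test_regular_hexagon_closed_form(self):
        perim, area, sf = landmark_polygon_descriptors(regular_hexagon())
        assert perim == pytest.approx(6.0)
        assert area == pytest.approx(3 * math.sqrt(3) / 2)
        assert sf == pytest.approx(3 * math.sqrt(3) / 2 / 36)
        assert sf == pytest.approx(0.07217, abs=5e-6)

    def test_shape_factor_below_disc_bound(self, landmark_set):
        _, _, sf = landmark_polygon_descriptors(landmark_set)
        assert 0.0 < sf < 1 / (4 * math.pi)

    def test_degenerate_rejected(self):
        collinear = LandmarkSet.from_array(
            np.column_stack([np.arange(6.0), np.arange(6.0)]), "photo", "s")
        with pytest.raises(DegenerateGeometryError):
            landmark_polygon_descriptors(collinear)


class TestMoments:
    def test_translation_invariance(self, landmark_set):
        xy = landmark_set.as_array()
        m0 = moment_invariants(landmark_set)
        m1 = moment_invariants(LandmarkSet.from_array(xy + [123.4, -56.7],
                                                      "photo", "s"))
        assert np.allclose(m0, m1, atol=1e-9)

    def test_rotation_scale_invariance(self, landmark_set):
        xy = landmark_set.as_array()
        m0 = moment_invariants(landmark_set)
        m1 = moment_invariants(LandmarkSet.from_array(
            similarity(xy, 2.3, math.radians(37), [3, 4]), "photo", "s"))
        assert np.allclose(m1, m0, rtol=1e-6)

    def test_mirror_flips_seventh_only(self, landmark_set):
        xy = landmark_set.as_array()
        m0 = moment_invariants(landmark_set)
        m1 = moment_invariants(LandmarkSet.from_array(xy * [-1, 1], "photo", "s"))
        assert np.allclose(m1[:6], m0[:6], rtol=1e-6)
        assert m1[6] == pytest.approx(-m0[6], rel=1e-6)

    def test_exact_moments_match_raster_oracle(self):
        # independent oracle: rasterize the filled polygon at high
        # resolution and compute image Hu moments with scikit-image
        from skimage.draw import polygon as sk_polygon
        from skimage.measure import moments_central, moments_hu, moments_normalized

        xy = canonical_order(np.array(
            [[0, 0], [8, 1], [12, 5], [9, 9], [3, 8], [1, 4]], float))
        exact = hu_moments(xy)
        scale = 60.0
        img = np.zeros((1000, 1000))
        rr, cc = sk_polygon((xy[:, 1] + 2) * scale, (xy[:, 0] + 2) * scale, img.shape)
        img[rr, cc] = 1.0
        raster = moments_hu(moments_normalized(moments_central(img)))
        assert np.allclose(raster[:6], exact[:6], rtol=2e-2)
        # row/column rasterization transposes the plane (a reflection), so
        # the seventh invariant is compared in magnitude only
        assert abs(raster[6]) == pytest.approx(abs(exact[6]), rel=5e-2)


class TestComputeDescriptors:
    def test_compositional_consistency(self, landmark_set):
        d = compute_descriptors(landmark_set)
        assert np.allclose(d.absolute_distances, absolute_distances(landmark_set))
        assert np.allclose(d.relative_distances,
                           relative_distances(d.absolute_distances))
        perim, area, sf = landmark_polygon_descriptors(landmark_set)
        assert (d.perimeter, d.area, d.shape_factor) == (perim, area, sf)
        assert np.allclose(d.moments, moment_invariants(landmark_set))

    def test_deterministic(self, landmark_set):
        d1 = compute_descriptors(landmark_set)
        d2 = compute_descriptors(landmark_set)
        assert np.array_equal(d1.absolute_distances, d2.absolute_distances)
        assert np.array_equal(d1.moments, d2.moments)
        assert d1.shape_factor == d2.shape_factor

    def test_invariance_and_scaling_suite(self, landmark_set, rng):
        # relative distances, shape factor and moments are similarity
        # invariant; absolute distances and perimeter scale as k, area as k^2
        d0 = compute_descriptors(landmark_set)
        xy = landmark_set.as_array()
        for _ in range(100):
            k = float(rng.uniform(0.2, 5.0))
            th = float(rng.uniform(0, 2 * np.pi))
            t = rng.normal(0, 50, 2)
            lm = LandmarkSet.from_array(similarity(xy, k, th, t), "photo", "s")
            d = compute_descriptors(lm)
            assert np.allclose(d.relative_distances, d0.relative_distances,
                               rtol=1e-6, atol=1e-9)
            assert d.shape_factor == pytest.approx(d0.shape_factor, rel=1e-6)
            assert np.allclose(d.moments, d0.moments, rtol=1e-6, atol=1e-8)
            assert np.allclose(d.absolute_distances, k * d0.absolute_distances,
                               rtol=1e-9)
            assert d.perimeter == pytest.approx(k * d0.perimeter, rel=1e-9)
            assert d.area == pytest.approx(k**2 * d0.area, rel=1e-9)

    def test_column_names_and_row(self, landmark_set):
        d = compute_descriptors(landmark_set)
        row = d.to_row()
        assert row["subject_id"] == "P0"
        assert "abs_d_1_2" in row and "mom_7" in row and "shape_factor" in row
        assert len(d.column_names) == 15 + 15 + 3 + 7
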