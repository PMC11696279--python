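"""Reference-line protocol, line-ruga intersection and similarity alignment."""

import math

import numpy as np
import pytest

from rugometry.exceptions import (
    DegenerateGeometryError,
    InvalidInputError,
    NoIntersectionError,
)
from rugometry.geometry import Point2D
from rugometry.landmarks import (
    IncisorFrame,
    LandmarkSet,
    ReferenceLine,
    RugaCurve,
    align_similarity,
    build_reference_lines,
    extract_landmarks,
    intersect_line_ruga,
)


def make_frame(xs=(-9.0, -4.0, 4.0, 9.0), direction=(0.0, 1.0)):
    return IncisorFrame(
        collar_11=Point2D(xs[1], 0.0), collar_12=Point2D(xs[0], 0.0),
        collar_21=Point2D(xs[2], 0.0), collar_22=Point2D(xs[3], 0.0),
        interincisal=Point2D(0.0, 0.0), sagittal_dir=direction,
    )


def straight_ruga(y, index, x0=-20.0, x1=20.0, n=9):
    xs = np.linspace(x0, x1, n)
    return RugaCurve(tuple(Point2D(float(x), float(y)) for x in xs), index=index)


class TestReferenceLines:
    def test_axis_aligned_positions(self):
        lines = build_reference_lines(make_frame())
        assert len(lines) == 5
        assert [ln.label for ln in lines] == ["interincisal", "1.1", "1.2", "2.1", "2.2"]
        assert sorted(ln.point.x for ln in lines) == [-9.0, -4.0, 0.0, 4.0, 9.0]
        for ln in lines:
            assert ln.direction == (0.0, 1.0)

    def test_rotation_equivariance(self):
        th = math.radians(30)
        d = (math.sin(th), math.cos(th))
        lines = build_reference_lines(make_frame(direction=d))
        dirs = {ln.direction for ln in lines}
        assert len(dirs) == 1  # all five remain mutually parallel
        assert next(iter(dirs)) == pytest.approx(d)

    def test_zero_direction_rejected(self):
        with pytest.raises(InvalidInputError):
            make_frame(direction=(0.0, 0.0))

    def test_duplicate_collars_rejected(self):
        with pytest.raises(InvalidInputError):
            IncisorFrame(collar_11=Point2D(1, 0), collar_12=Point2D(1, 0),
                         collar_21=Point2D(2, 0), collar_22=Point2D(3, 0),
                         interincisal=Point2D(0, 0), sagittal_dir=(0, 1))


class TestIntersection:
    def test_simple_crossing(self):
        line = ReferenceLine(Point2D(1.0, 0.0), (0.0, 1.0))
        ruga = RugaCurve((Point2D(0, 2), Point2D(3, 2)), index=1)
        p = intersect_line_ruga(line, ruga)
        assert (p.x, p.y) == pytest.approx((1.0, 2.0))

    def test_miss_raises_with_labels(self):
        line = ReferenceLine(Point2D(50.0, 0.0), (0.0, 1.0), label="1.1")
        with pytest.raises(NoIntersectionError) as exc:
            intersect_line_ruga(line, straight_ruga(5.0, 1))
        assert exc.value.line_label == "1.1"
        assert exc.value.ruga_index == 1

    def test_multiple_crossings_choose_anterior(self, rng):
        # wavy polyline crossing a vertical line several times: the chosen
        # point must match a brute-force scan over all segment crossings
        xs = np.linspace(-10, 10, 201)
        for seed in range(20):
            r = np.random.default_rng(seed)
            ys = 6 + 3 * np.sin(xs * r.uniform(0.5, 2.0)) + r.normal(0, 0.2, xs.size)
            pts = np.column_stack([ys, xs])  # polyline running in y, crossing x-lines
            ruga = RugaCurve(tuple(Point2D(*p) for p in pts), index=1)
            line = ReferenceLine(Point2D(6.0, 0.0), (0.0, 1.0))
            got = intersect_line_ruga(line, ruga)
            # oracle: parametric crossing of every segment with x = 6
            best = None
            for a, b in zip(pts[:-1], pts[1:]):
                if (a[0] - 6.0) * (b[0] - 6.0) <= 0 and a[0] != b[0]:
                    t = (6.0 - a[0]) / (b[0] - a[0])
                    y = a[1] + t * (b[1] - a[1])
                    if best is None or y < best:
                        best = y
            assert best is not None
            assert got.y == pytest.approx(best, abs=1e-9)


class TestExtractLandmarks:
    def test_straight_rugae_rows(self):
        frame = make_frame()
        lm = extract_landmarks(frame, straight_ruga(5.0, 1), straight_ruga(11.0, 2),
                               "photo", "S1")
        ys = [p.y for p in lm.pts]
        assert ys[:4] == pytest.approx([5.0] * 4)
        assert ys[4:] == pytest.approx([11.0] * 2)
        # protocol order: 2.1, 2.2, 1.1, 1.2 on ruga 1; 1.1, 2.2 on ruga 2
        assert [p.x for p in lm.pts] == pytest.approx([4, 9, -4, -9, -4, 9])

    def test_out_of_span_names_landmarks(self):
        frame = make_frame(xs=(-30.0, -4.0, 4.0, 30.0))
        with pytest.raises(NoIntersectionError) as exc:
            extract_landmarks(frame, straight_ruga(5.0, 1), straight_ruga(11.0, 2),
                              "photo", "S1")
        # lines through 1.2 (x=-30) and 2.2 (x=30) miss: landmarks 2, 4, 6
        assert "2, 4, 6" in str(exc.value)

    def test_wrong_ruga_indices_rejected(self):
        frame = make_frame()
        with pytest.raises(InvalidInputError):
            extract_landmarks(frame, straight_ruga(5.0, 2), straight_ruga(11.0, 2),
                              "photo", "S1")

    def test_recovers_generator_ground_truth(self, palate):
        lm = extract_landmarks(palate.frame, palate.rugae[0], palate.rugae[1],
                               "photo", "P0")
        err = np.abs(lm.as_array() - palate.true_landmarks.as_array()).max()
        assert err < 1e-9

    def test_similarity_equivariance(self, palate):
        th = math.radians(20)
        k = 1.7
        R = k * np.array([[math.cos(th), -math.sin(th)],
                          [math.sin(th), math.cos(th)]])
        t = np.array([5.0, -3.0])

        def tf(p: Point2D) -> Point2D:
            v = R @ p.as_array() + t
            return Point2D(float(v[0]), float(v[1]))

        f = palate.frame
        d = R @ np.asarray(f.sagittal_dir)
        frame2 = IncisorFrame(tf(f.collar_11), tf(f.collar_12), tf(f.collar_21),
                              tf(f.collar_22), tf(f.interincisal),
                              tuple(d / np.linalg.norm(d)))
        rugae2 = [RugaCurve(tuple(tf(p) for p in r.points), r.index)
                  for r in palate.rugae[:2]]
        lm1 = extract_landmarks(f, palate.rugae[0], palate.rugae[1], "photo", "P0")
        lm2 = extract_landmarks(frame2, rugae2[0], rugae2[1], "photo", "P0")
        expected = lm1.as_array() @ R.T + t
        assert np.allclose(lm2.as_array(), expected, atol=1e-8)


class TestAlignSimilarity:
    def test_identity_on_self(self, landmark_set):
        aligned, tf = align_similarity(landmark_set, landmark_set)
        assert tf.scale == pytest.approx(1.0, abs=1e-12)
        assert tf.rotation == pytest.approx(0.0, abs=1e-12)
        assert tf.residual == pytest.approx(0.0, abs=1e-18)
        assert np.allclose(aligned.as_array(), landmark_set.as_array())

    def test_exact_recovery_of_rotation_and_scale(self, landmark_set):
        th = math.radians(25)
        k = 1.5
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        moved = LandmarkSet.from_array(
            k * landmark_set.as_array() @ R.T + [2.0, -7.0], "scan", "P0")
        _, tf = align_similarity(landmark_set, moved)
        assert tf.rotation_deg == pytest.approx(25.0, abs=1e-9)
        assert tf.scale == pytest.approx(1.5, rel=1e-12)
        assert tf.residual < 1e-9

    def test_closed_form_beats_grid_search_oracle(self, landmark_set, rng):
        # closed-form residual must equal the optimum of an independent
        # hierarchical grid search over (scale, rotation)
        X = landmark_set.as_array()
        Y = 1.2 * X + rng.normal(0, 0.4, X.shape)
        fixed = LandmarkSet.from_array(Y, "scan", "P0")
        _, tf = align_similarity(landmark_set, fixed)

        def residual(s, th):
            R = s * np.array([[math.cos(th), -math.sin(th)],
                              [math.sin(th), math.cos(th)]])
            Xr = X @ R.T
            t = Y.mean(axis=0) - Xr.mean(axis=0)  # optimal translation closed form
            return float(((Xr + t - Y) ** 2).sum())

        s_lo, s_hi, t_lo, t_hi = 0.5, 2.5, -math.pi / 2, math.pi / 2
        best = np.inf
        for _ in range(6):  # hierarchical refinement
            ss = np.linspace(s_lo, s_hi, 21)
            ts = np.linspace(t_lo, t_hi, 21)
            vals = [(residual(s, t), s, t) for s in ss for t in ts]
            best, s_best, t_best = min(vals)
            ds, dt = ss[1] - ss[0], ts[1] - ts[0]
            s_lo, s_hi = s_best - ds, s_best + ds
            t_lo, t_hi = t_best - dt, t_best + dt
        assert tf.residual <= best + 1e-9
        assert tf.residual == pytest.approx(best, abs=1e-6)

    def test_residual_swap_scale_symmetry(self, rng):
        for _ in range(5):
            A = rng.normal(0, 5, (6, 2))
            B = 1.3 * A + rng.normal(0, 0.3, (6, 2)) + 4.0
            a = LandmarkSet.from_array(A, "photo", "s")
            b = LandmarkSet.from_array(B, "scan", "s")
            _, t_ab = align_similarity(a, b)
            _, t_ba = align_similarity(b, a)
            assert t_ab.residual == pytest.approx(
                t_ba.residual * t_ab.scale**2, rel=0.05)

    def test_coincident_points_rejected(self):
        flat = LandmarkSet.from_array(np.ones((6, 2)), "photo", "s")
        other = LandmarkSet.from_array(np.arange(12.0).reshape(6, 2), "scan", "s")
        with pytest.raises(DegenerateGeometryError):
            align_similarity(flat, other)
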