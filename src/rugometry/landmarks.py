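"""The six-landmark rugoscopy protocol and landmark alignment.

Five parallel reference lines are constructed for each palatal record: one
through the interincisal point and four through the central collar points of
the upper central and lateral incisors (FDI 1.1, 1.2, 2.1, 2.2), all running
along the mid-sagittal direction.  Intersecting these lines with the first
two palatal rugae yields six ordered landmarks:

    1. line through 2.1 x ruga 1      4. line through 1.2 x ruga 1
    2. line through 2.2 x ruga 1      5. line through 1.1 x ruga 2
    3. line through 1.1 x ruga 1      6. line through 2.2 x ruga 2

When a line crosses a curved ruga more than once, the anterior-most crossing
(closest to the incisors along the sagittal direction) is taken, since rugae
are read from the incisive papilla backward.

Two landmark configurations from different modalities (clinical photograph,
plaster model, intraoral scan) are superimposed by closed-form least-squares
similarity alignment (rotation + isotropic scale + translation, no
reflection), replacing the manual image superimposition of the original
operator protocol with a reproducible operation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateGeometryError,
    InvalidInputError,
    NoIntersectionError,
)
from .geometry import Point2D

__all__ = [
    "MODALITIES",
    "IncisorFrame",
    "RugaCurve",
    "LandmarkSet",
    "ReferenceLine",
    "SimilarityTransform",
    "build_reference_lines",
    "intersect_line_ruga",
    "extract_landmarks",
    "align_similarity",
]

MODALITIES = ("photo", "plaster", "scan")
#: modalities plus the synthetic ground-truth label
_ALLOWED_MODALITIES = MODALITIES + ("truth",)

#: landmark index (1-based) -> (reference line label, ruga index)
LANDMARK_PROTOCOL: tuple[tuple[str, int], ...] = (
    ("2.1", 1),
    ("2.2", 1),
    ("1.1", 1),
    ("1.2", 1),
    ("1.1", 2),
    ("2.2", 2),
)


@dataclass(frozen=True)
class IncisorFrame:
    """Anchor points of the reference-line protocol for one palatal record.

    ``collar_11`` .. ``collar_22`` are the central points of the gingival
    collars of the four upper incisors (FDI notation); ``interincisal`` the
    midpoint between the central incisors; ``sagittal_dir`` the unit
    mid-sagittal direction the five lines run along.
    """

    collar_11: Point2D
    collar_12: Point2D
    collar_21: Point2D
    collar_22: Point2D
    interincisal: Point2D
    sagittal_dir: tuple[float, float]

    def __post_init__(self) -> None:
        d = np.asarray(self.sagittal_dir, dtype=float)
        n = float(np.hypot(*d))
        if not np.isfinite(n) or n == 0.0:
            raise InvalidInputError("sagittal_dir must have nonzero finite norm")
        if abs(n - 1.0) > 1e-9:
            object.__setattr__(self, "sagittal_dir", (d[0] / n, d[1] / n))
        collars = [self.collar_11, self.collar_12, self.collar_21, self.collar_22]
        for a in range(4):
            for b in range(a + 1, 4):
                if collars[a] == collars[b]:
                    raise InvalidInputError("collar points must be pairwise distinct")

    def collar(self, tooth: str) -> Point2D:
        return {"1.1": self.collar_11, "1.2": self.collar_12,
                "2.1": self.collar_21, "2.2": self.collar_22}[tooth]


@dataclass(frozen=True)
class RugaCurve:
    """A palatal ruga as an ordered planar polyline.

    ``index`` counts rugae from the incisors (1 = first, 2 = second).
    """

    points: tuple[Point2D, ...]
    index: int

    def __init__(self, points, index: int):
        pts = tuple(points)
        if len(pts) < 2:
            raise InvalidInputError("a ruga polyline needs >= 2 points")
        for a, b in zip(pts, pts[1:]):
            if a == b:
                raise InvalidInputError("consecutive ruga points must be distinct")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "index", int(index))

    def as_array(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.points], dtype=float)


@dataclass(frozen=True)
class LandmarkSet:
    """The six ordered protocol landmarks of one palatal record."""

    pts: tuple[Point2D, ...]
    modality: str
    subject_id: str

    def __post_init__(self) -> None:
        if len(self.pts) != 6:
            raise InvalidInputError(f"a LandmarkSet has exactly 6 points, got {len(self.pts)}")
        if self.modality not in _ALLOWED_MODALITIES:
            raise InvalidInputError(
                f"modality must be one of {_ALLOWED_MODALITIES}, got {self.modality!r}")

    def as_array(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.pts], dtype=float)

    @classmethod
    def from_array(cls, xy, modality: str, subject_id: str) -> "LandmarkSet":
        arr = np.asarray(xy, dtype=float)
        if arr.shape != (6, 2):
            raise InvalidInputError(f"expected shape (6, 2), got {arr.shape}")
        return cls(tuple(Point2D(float(x), float(y)) for x, y in arr), modality, subject_id)


@dataclass(frozen=True)
class ReferenceLine:
    """An infinite line through ``point`` along unit ``direction``."""

    point: Point2D
    direction: tuple[float, float]
    label: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = float(np.hypot(*d))
        if not np.isfinite(n) or n == 0.0:
            raise InvalidInputError("line direction must have nonzero finite norm")
        if abs(n - 1.0) > 1e-12:
            object.__setattr__(self, "direction", (d[0] / n, d[1] / n))


def build_reference_lines(frame: IncisorFrame) -> tuple[ReferenceLine, ...]:
    """The five parallel reference lines of the protocol.

    Returns lines labelled ``interincisal``, ``1.1``, ``1.2``, ``2.1``,
    ``2.2``, all parallel to ``frame.sagittal_dir``.
    """
    d = frame.sagittal_dir
    return (
        ReferenceLine(frame.interincisal, d, "interincisal"),
        ReferenceLine(frame.collar_11, d, "1.1"),
        ReferenceLine(frame.collar_12, d, "1.2"),
        ReferenceLine(frame.collar_21, d, "2.1"),
        ReferenceLine(frame.collar_22, d, "2.2"),
    )


def _line_polyline_crossings(line: ReferenceLine, xy: np.ndarray) -> np.ndarray:
    """All intersection points of an infinite line with a polyline, (m, 2)."""
    p = np.array([line.point.x, line.point.y])
    d = np.asarray(line.direction)
    normal = np.array([-d[1], d[0]])
    f = (xy - p) @ normal  # signed distance of each vertex from the line
    pts: list[np.ndarray] = []
    for i in range(len(xy) - 1):
        fa, fb = f[i], f[i + 1]
        if fa == 0.0 and fb == 0.0:  # segment lies on the line; take endpoints
            pts.extend([xy[i], xy[i + 1]])
        elif fa == 0.0:
            pts.append(xy[i])
        elif fb == 0.0:
            if i == len(xy) - 2:
                pts.append(xy[i + 1])
        elif (fa > 0) != (fb > 0):
            t = fa / (fa - fb)
            pts.append(xy[i] + t * (xy[i + 1] - xy[i]))
    if not pts:
        return np.empty((0, 2))
    out = np.array(pts)
    # dedupe nearly identical crossings (shared segment endpoints)
    keep = [0]
    for i in range(1, len(out)):
        if np.linalg.norm(out[i] - out[keep[-1]]) > 1e-12:
            keep.append(i)
    return out[keep]


def intersect_line_ruga(line: ReferenceLine, ruga: RugaCurve) -> Point2D:
    """Intersection of a reference line with a ruga polyline.

    If the line crosses the polyline more than once, the anterior-most
    crossing — smallest coordinate along the line's direction, measured from
    the line's anchor point — is returned.  Raises
    :class:`NoIntersectionError` when they do not meet.
    """
    xy = ruga.as_array()
    crossings = _line_polyline_crossings(line, xy)
    if len(crossings) == 0:
        raise NoIntersectionError(
            f"line {line.label or '<unlabelled>'} does not cross ruga {ruga.index}",
            line_label=line.label, ruga_index=ruga.index,
        )
    p = np.array([line.point.x, line.point.y])
    d = np.asarray(line.direction)
    along = (crossings - p) @ d
    best = crossings[int(np.argmin(along))]
    return Point2D(float(best[0]), float(best[1]))


def extract_landmarks(frame: IncisorFrame, ruga1: RugaCurve, ruga2: RugaCurve,
                      modality: str, subject_id: str) -> LandmarkSet:
    """Run the full protocol: reference lines -> six ordered landmarks."""
    if ruga1.index != 1 or ruga2.index != 2:
        raise InvalidInputError("expected rugae with index 1 and 2")
    lines = {ln.label: ln for ln in build_reference_lines(frame)}
    rugae = {1: ruga1, 2: ruga2}
    pts: list[Point2D] = []
    failures: list[int] = []
    for idx, (tooth, ruga_idx) in enumerate(LANDMARK_PROTOCOL, start=1):
        try:
            pts.append(intersect_line_ruga(lines[tooth], rugae[ruga_idx]))
        except NoIntersectionError:
            failures.append(idx)
    if failures:
        raise NoIntersectionError(
            f"no line-ruga intersection for landmark(s) {failures} "
            f"(subject {subject_id!r}, modality {modality!r})",
            landmark_index=failures[0],
        )
    return LandmarkSet(tuple(pts), modality, subject_id)


@dataclass(frozen=True)
class SimilarityTransform:
    """A direct similarity ``x -> scale * R(rotation) @ x + translation``."""

    scale: float
    rotation: float  # radians, counter-clockwise
    translation: tuple[float, float]
    residual: float = 0.0  # sum of squared point distances after alignment

    @property
    def rotation_deg(self) -> float:
        return math.degrees(self.rotation)

    @property
    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, xy: np.ndarray) -> np.ndarray:
        return np.asarray(xy, dtype=float) @ self.matrix.T + np.asarray(self.translation)


def align_similarity(moving: LandmarkSet, fixed: LandmarkSet
                     ) -> tuple[LandmarkSet, SimilarityTransform]:
    """Least-squares similarity superimposition of two landmark sets.

    Finds the rotation, isotropic scale and translation minimizing the sum
    of squared distances between corresponding landmarks (closed form via
    the cross-covariance SVD); reflections are excluded as anatomically
    meaningless.  Returns the transformed moving set and the transform,
    whose ``residual`` is the minimized sum of squares.
    """
    X = moving.as_array()
    Y = fixed.as_array()
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mx, Y - my
    var_x = float((Xc**2).sum()) / len(X)
    if var_x == 0.0:
        raise DegenerateGeometryError("all moving landmarks coincide; alignment undefined")
    cov = (Yc.T @ Xc) / len(X)
    U, S, Vt = np.linalg.svd(cov)
    d = np.ones(2)
    if np.linalg.det(U @ Vt) < 0:  # forbid reflection
        d[-1] = -1.0
    R = U @ np.diag(d) @ Vt
    scale = float((S * d).sum()) / var_x
    t = my - scale * (R @ mx)
    rotation = math.atan2(R[1, 0], R[0, 0])
    aligned_xy = scale * (X @ R.T) + t
    residual = float(((aligned_xy - Y) ** 2).sum())
    tf = SimilarityTransform(scale, rotation, (float(t[0]), float(t[1])), residual)
    aligned = LandmarkSet.from_array(aligned_xy, moving.modality, moving.subject_id)
    return aligned, tf
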