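"""Primitive planar geometry for landmark morphometrics.

Triangle area is computed as half the absolute value of the determinant of
the homogeneous coordinate matrix

    area = 1/2 |det [[x_i, y_i, 1], [x_j, y_j, 1], [x_k, y_k, 1]]|

and the compactness index (shape factor) as ``area / perimeter**2`` — a
dimensionless, similarity-invariant measure of how compact a figure is,
maximal (1/(4*pi)) in the circular limit.  Polygon area is obtained by fan
triangulation into signed triangle areas, which agrees with the shoelace
formula on simple polygons.

Coordinates are unit-agnostic (mm or px); the image convention of y growing
downward is accepted throughout, since every quantity here is invariant to
that choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import DegenerateGeometryError, InvalidInputError

__all__ = [
    "Point2D",
    "Triangle",
    "Polygon",
    "triangle_area",
    "perimeter",
    "compactness_index",
    "polygon_area",
    "canonical_order",
]

# Relative tolerance below which an area is treated as exactly zero:
# area < DEGENERATE_REL_TOL * (bounding-box diagonal)^2.
DEGENERATE_REL_TOL = 1e-12


@dataclass(frozen=True)
class Point2D:
    """A planar point with finite coordinates (arbitrary consistent unit)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidInputError(f"non-finite coordinates ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class Triangle:
    """Three vertices; degenerate (collinear) triangles are permitted."""

    i: Point2D
    j: Point2D
    k: Point2D

    @property
    def vertices(self) -> tuple[Point2D, Point2D, Point2D]:
        return (self.i, self.j, self.k)


@dataclass(frozen=True)
class Polygon:
    """An ordered vertex list (length >= 3).

    The stored order is whatever the caller supplied; pass the vertices
    through :func:`canonical_order` (sort by angle about the centroid)
    before area computations to guarantee a simple boundary.
    """

    vertices: tuple[Point2D, ...]

    def __init__(self, vertices: Iterable[Point2D]):
        verts = tuple(vertices)
        if len(verts) < 3:
            raise InvalidInputError(f"polygon needs >= 3 vertices, got {len(verts)}")
        object.__setattr__(self, "vertices", verts)

    def as_array(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.vertices], dtype=float)


def _coords(obj: Polygon | Triangle | Sequence[Point2D] | np.ndarray) -> np.ndarray:
    if isinstance(obj, Triangle):
        return np.array([[p.x, p.y] for p in obj.vertices], dtype=float)
    if isinstance(obj, Polygon):
        return obj.as_array()
    arr = np.asarray(
        [[p.x, p.y] for p in obj] if len(obj) and isinstance(obj[0], Point2D) else obj,
        dtype=float,
    )
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidInputError(f"expected an (n, 2) coordinate array, got {arr.shape}")
    if not np.isfinite(arr).all():
        raise InvalidInputError("non-finite coordinates")
    return arr


def _bbox_diag_sq(xy: np.ndarray) -> float:
    span = xy.max(axis=0) - xy.min(axis=0)
    return float(span @ span)


def triangle_area(t: Triangle) -> float:
    """Area of a triangle via the homogeneous-coordinate determinant.

    Returns half the absolute value of ``det [[x,y,1] x 3]``; zero for
    collinear vertices (degenerate areas below the relative tolerance are
    snapped to exactly 0).
    """
    xy = _coords(t)
    m = np.column_stack([xy, np.ones(3)])
    area = 0.5 * abs(float(np.linalg.det(m)))
    if area < DEGENERATE_REL_TOL * _bbox_diag_sq(xy):
        return 0.0
    return area


def perimeter(p: Polygon | Triangle) -> float:
    """Sum of consecutive edge lengths, including the closing edge."""
    xy = _coords(p)
    diffs = np.diff(np.vstack([xy, xy[:1]]), axis=0)
    return float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())


def compactness_index(area: float, perim: float) -> float:
    """Shape factor ``area / perim**2``; dimensionless and similarity-invariant.

    Raises :class:`DegenerateGeometryError` when the perimeter is zero
    (all points coincident), where the ratio is undefined.
    """
    if perim < 0:
        raise InvalidInputError(f"negative perimeter {perim}")
    if perim == 0.0:
        raise DegenerateGeometryError("zero perimeter: compactness undefined")
    return area / perim**2


def canonical_order(vertices: Sequence[Point2D] | np.ndarray) -> np.ndarray:
    """Sort vertices counter-clockwise by angle about their centroid.

    Angular order about an interior point yields a simple (star-shaped)
    boundary regardless of the input sequence; ties in angle are broken by
    radius.  Returns an (n, 2) float array.
    """
    xy = _coords(vertices)
    c = xy.mean(axis=0)
    d = xy - c
    ang = np.arctan2(d[:, 1], d[:, 0])
    r = np.hypot(d[:, 0], d[:, 1])
    order = np.lexsort((r, ang))
    return xy[order]


def _signed_area(xy: np.ndarray) -> float:
    # fan triangulation from vertex 0: sum of signed homogeneous determinants
    total = 0.0
    x0, y0 = xy[0]
    for a, b in zip(xy[1:-1], xy[2:]):
        m = np.array([[x0, y0, 1.0], [a[0], a[1], 1.0], [b[0], b[1], 1.0]])
        total += 0.5 * float(np.linalg.det(m))
    return total


def polygon_area(p: Polygon | Sequence[Point2D] | np.ndarray, *,
                 canonicalize: bool = True) -> float:
    """Area of a polygon by fan triangulation into determinant triangle areas.

    With ``canonicalize=True`` (default) vertices are first put in angular
    order about their centroid; the result then equals the shoelace value of
    the canonical boundary.  A boundary that remains self-intersecting, or a
    polygon collapsed below the degeneracy tolerance, raises
    :class:`DegenerateGeometryError`.
    """
    xy = canonical_order(p) if canonicalize else _coords(p)
    area = abs(_signed_area(xy))
    diag_sq = _bbox_diag_sq(xy)
    if diag_sq == 0.0:
        raise DegenerateGeometryError("all polygon vertices coincide")
    import shapely.geometry as _sg

    if not _sg.LinearRing(xy).is_simple:
        # collinear rings are flagged non-simple too; those are degenerate
        # but valid (zero area), unlike a genuinely crossing boundary
        centered = xy - xy.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9 * np.sqrt(diag_sq)) < 2:
            return 0.0
        raise DegenerateGeometryError("self-intersecting polygon boundary")
    if area < DEGENERATE_REL_TOL * diag_sq:
        return 0.0
    return area
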