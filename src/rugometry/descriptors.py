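"""The six descriptor families computed from one six-landmark configuration.

For a landmark set L = {P1..P6} the families are:

* **absolute distances** — the 15 Euclidean distances over all unordered
  landmark pairs, in lexicographic pair order (1,2), (1,3), ..., (5,6);
* **relative distances** — the same vector divided by its maximum entry,
  making the family scale-free (so photograph / cast / scan magnification
  differences cancel); the maximum entry is exactly 1;
* **perimeter** and **area** of the polygon obtained by joining the
  landmarks (vertices in canonical angular order about their centroid);
* **shape factor** — the compactness index area / perimeter², dimensionless
  and similarity-invariant, in (0, 1/(4π)];
* **moments** — Hu's seven invariant moments of the filled landmark
  polygon, computed from *exact* polygon moments (Green's-theorem
  integration of x^p y^q over the region, no rasterization), reported on a
  signed-log10 scale for numeric comparability across their many orders of
  magnitude.  The first six are invariant under any similarity transform;
  the seventh changes sign under reflection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .exceptions import DegenerateGeometryError
from .geometry import canonical_order, compactness_index, polygon_area
from .landmarks import LandmarkSet

__all__ = [
    "PAIR_ORDER",
    "DescriptorSet",
    "absolute_distances",
    "relative_distances",
    "landmark_polygon_descriptors",
    "polygon_raw_moments",
    "hu_moments",
    "moment_invariants",
    "compute_descriptors",
]

#: the 15 unordered landmark pairs in fixed lexicographic order (1-based)
PAIR_ORDER: tuple[tuple[int, int], ...] = tuple(
    (i + 1, j + 1) for i, j in combinations(range(6), 2)
)

FAMILIES = ("absolute_distances", "relative_distances", "perimeter", "area",
            "shape_factor", "moments")


@dataclass(frozen=True)
class DescriptorSet:
    """All six descriptor families of one landmark configuration."""

    absolute_distances: np.ndarray  # (15,), length units
    relative_distances: np.ndarray  # (15,), dimensionless, max exactly 1
    perimeter: float
    area: float
    shape_factor: float
    moments: np.ndarray  # (7,), signed-log10 Hu invariants
    modality: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "absolute_distances",
                           np.asarray(self.absolute_distances, dtype=float))
        object.__setattr__(self, "relative_distances",
                           np.asarray(self.relative_distances, dtype=float))
        object.__setattr__(self, "moments", np.asarray(self.moments, dtype=float))
        if self.absolute_distances.shape != (15,) or self.relative_distances.shape != (15,):
            raise ValueError("distance families must have exactly 15 entries")
        if self.moments.shape != (7,):
            raise ValueError("moment family must have exactly 7 entries")

    @property
    def column_names(self) -> list[str]:
        names = [f"abs_d_{i}_{j}" for i, j in PAIR_ORDER]
        names += [f"rel_d_{i}_{j}" for i, j in PAIR_ORDER]
        names += ["perimeter", "area", "shape_factor"]
        names += [f"mom_{k}" for k in range(1, 8)]
        return names

    def to_row(self) -> dict[str, float]:
        """Flat family-prefixed mapping, one row per (subject, modality)."""
        vals = np.concatenate([
            self.absolute_distances, self.relative_distances,
            [self.perimeter, self.area, self.shape_factor], self.moments,
        ])
        row: dict[str, object] = {"subject_id": self.subject_id, "modality": self.modality}
        row.update(zip(self.column_names, (float(v) for v in vals)))
        return row


def absolute_distances(lm: LandmarkSet) -> np.ndarray:
    """The 15 pairwise Euclidean distances, lexicographic pair order."""
    xy = lm.as_array()
    return np.array([np.hypot(*(xy[i - 1] - xy[j - 1])) for i, j in PAIR_ORDER])


def relative_distances(abs_d: np.ndarray) -> np.ndarray:
    """Distances normalized by the maximum pairwise distance (scale-free)."""
    abs_d = np.asarray(abs_d, dtype=float)
    m = abs_d.max()
    if m <= 0.0:
        raise DegenerateGeometryError("all pairwise distances are zero")
    return abs_d / m


def landmark_polygon_descriptors(lm: LandmarkSet) -> tuple[float, float, float]:
    """(perimeter, area, shape factor) of the canonical landmark polygon."""
    xy = canonical_order(lm.as_array())
    area = polygon_area(xy, canonicalize=False)
    diffs = np.diff(np.vstack([xy, xy[:1]]), axis=0)
    perim = float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())
    if area == 0.0 or perim == 0.0:
        raise DegenerateGeometryError("degenerate landmark polygon (zero area or perimeter)")
    return perim, area, compactness_index(area, perim)


def polygon_raw_moments(xy: np.ndarray, max_order: int = 3) -> dict[tuple[int, int], float]:
    """Exact raw moments m_pq = ∬ x^p y^q dA over a simple polygon.

    The region is fan-triangulated from the origin into signed triangles
    O-V_i-V_{i+1}; on each, the monomial integral has the closed form

        ∬_T x^p y^q dA = det(V_i, V_{i+1}) · Σ_{a,b} C(p,a) C(q,b)
            x_i^a x_{i+1}^{p-a} y_i^b y_{i+1}^{q-b} ·
            (a+b)! (p+q-a-b)! / (p+q+2)!

    obtained by mapping the triangle to the unit simplex.  Signed triangle
    contributions make the result exact for any simple polygon regardless
    of where the origin lies; a clockwise boundary is sign-corrected so
    that m00 (the area) is positive.
    """
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    moments = {(p, q): 0.0 for p in range(max_order + 1) for q in range(max_order + 1)
               if p + q <= max_order}
    for i in range(n):
        x1, y1 = xy[i]
        x2, y2 = xy[(i + 1) % n]
        det = x1 * y2 - x2 * y1
        if det == 0.0:
            continue
        for (p, q) in moments:
            s = 0.0
            for a in range(p + 1):
                for b in range(q + 1):
                    s += (math.comb(p, a) * math.comb(q, b)
                          * x1**a * x2**(p - a) * y1**b * y2**(q - b)
                          * math.factorial(a + b) * math.factorial(p + q - a - b))
            moments[(p, q)] += det * s / math.factorial(p + q + 2)
    if moments[(0, 0)] < 0:  # clockwise boundary
        moments = {k: -v for k, v in moments.items()}
    return moments


def hu_moments(xy: np.ndarray) -> np.ndarray:
    """Hu's seven invariants of the filled polygon, raw (unlogged) scale."""
    m = polygon_raw_moments(xy)
    m00 = m[(0, 0)]
    if m00 <= 0.0:
        raise DegenerateGeometryError("polygon has zero area; moments undefined")
    xc, yc = m[(1, 0)] / m00, m[(0, 1)] / m00
    mu20 = m[(2, 0)] - xc * m[(1, 0)]
    mu02 = m[(0, 2)] - yc * m[(0, 1)]
    mu11 = m[(1, 1)] - xc * m[(0, 1)]
    mu30 = m[(3, 0)] - 3 * xc * m[(2, 0)] + 2 * xc**2 * m[(1, 0)]
    mu21 = m[(2, 1)] - 2 * xc * m[(1, 1)] - yc * m[(2, 0)] + 2 * xc**2 * m[(0, 1)]
    mu12 = m[(1, 2)] - 2 * yc * m[(1, 1)] - xc * m[(0, 2)] + 2 * yc**2 * m[(1, 0)]
    mu03 = m[(0, 3)] - 3 * yc * m[(0, 2)] + 2 * yc**2 * m[(0, 1)]

    def eta(mu: float, order: int) -> float:
        return mu / m00 ** (1 + order / 2)

    n20, n02, n11 = eta(mu20, 2), eta(mu02, 2), eta(mu11, 2)
    n30, n21, n12, n03 = eta(mu30, 3), eta(mu21, 3), eta(mu12, 3), eta(mu03, 3)

    h1 = n20 + n02
    h2 = (n20 - n02) ** 2 + 4 * n11**2
    h3 = (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2
    h4 = (n30 + n12) ** 2 + (n21 + n03) ** 2
    h5 = ((n30 - 3 * n12) * (n30 + n12)
          * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2)
          + (3 * n21 - n03) * (n21 + n03)
          * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2))
    h6 = ((n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2)
          + 4 * n11 * (n30 + n12) * (n21 + n03))
    h7 = ((3 * n21 - n03) * (n30 + n12)
          * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2)
          - (n30 - 3 * n12) * (n21 + n03)
          * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2))
    return np.array([h1, h2, h3, h4, h5, h6, h7])


def signed_log10(values: np.ndarray) -> np.ndarray:
    """sign(v) * log10(|v|); exact zeros map to 0."""
    values = np.asarray(values, dtype=float)
    out = np.zeros_like(values)
    nz = values != 0.0
    out[nz] = np.sign(values[nz]) * np.log10(np.abs(values[nz]))
    return out


def moment_invariants(lm: LandmarkSet) -> np.ndarray:
    """Signed-log10 Hu moments of the filled canonical landmark polygon."""
    xy = canonical_order(lm.as_array())
    if polygon_area(xy, canonicalize=False) == 0.0:
        raise DegenerateGeometryError("degenerate landmark polygon; moments undefined")
    return signed_log10(hu_moments(xy))


def compute_descriptors(lm: LandmarkSet) -> DescriptorSet:
    """All six families for one landmark set, mutually consistent."""
    abs_d = absolute_distances(lm)
    rel_d = relative_distances(abs_d)
    perim, area, sf = landmark_polygon_descriptors(lm)
    moms = moment_invariants(lm)
    return DescriptorSet(abs_d, rel_d, perim, area, sf, moms,
                         modality=lm.modality, subject_id=lm.subject_id)
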