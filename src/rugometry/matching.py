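"""Pairwise comparison of descriptor sets via r and R².

Each descriptor family of one image is correlated (Pearson product-moment)
against the same family of the other image; the coefficient of
determination is R² = r².  Results are classified with ordinal bands:

* r:  < 0.3 weak, 0.3–0.7 moderate, > 0.7 strong;
* R²: 0 none, (0, 0.2) weak, [0.2, 0.4) moderate, [0.4, 0.6) strong,
  [0.6, 0.8) very strong, [0.8, 1.0] perfect.

The vector families (absolute distances, relative distances, moments) give
one coefficient per image pair.  The scalar polygon descriptors
(perimeter, area, shape factor) cannot yield a correlation alone; within a
pair they are pooled into one 3-vector per image — standardized per
component across the cohort when cohort statistics are available — while
study-report per-family coefficients for the scalars are computed across
cohort subjects (see :mod:`rugometry.agreement`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConstantVectorError, InvalidInputError
from .descriptors import DescriptorSet

__all__ = [
    "VECTOR_FAMILIES",
    "FamilyComparison",
    "ComparisonResult",
    "ScalarStandardizer",
    "family_correlation",
    "determination",
    "classify_r",
    "classify_R2",
    "compare_images",
]

VECTOR_FAMILIES = ("absolute_distances", "relative_distances", "moments")
POOLED_FAMILY = "polygon_scalars"  # perimeter, area, shape_factor pooled


def family_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError(f"need equal-length 1-d vectors, got {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise InvalidInputError(f"need length >= 3, got {len(a)}")
    ac = a - a.mean()
    bc = b - b.mean()
    va = float(ac @ ac)
    vb = float(bc @ bc)
    if va == 0.0 or vb == 0.0:
        raise ConstantVectorError("zero-variance vector: correlation undefined")
    r = float(ac @ bc) / np.sqrt(va * vb)
    return float(np.clip(r, -1.0, 1.0))


def determination(r: float) -> float:
    """Coefficient of determination R² = r²."""
    if not -1.0 <= r <= 1.0:
        raise InvalidInputError(f"r must lie in [-1, 1], got {r}")
    return r * r


def classify_r(r: float) -> str:
    """Ordinal band of a correlation coefficient."""
    if not np.isfinite(r):
        raise InvalidInputError("r must be finite")
    if r < 0.3:
        return "weak"
    if r <= 0.7:
        return "moderate"
    return "strong"


def classify_R2(R2: float) -> str:
    """Ordinal band of a determination coefficient."""
    if not 0.0 <= R2 <= 1.0:
        raise InvalidInputError(f"R2 must lie in [0, 1], got {R2}")
    if R2 == 0.0:
        return "none"
    if R2 < 0.2:
        return "weak"
    if R2 < 0.4:
        return "moderate"
    if R2 < 0.6:
        return "strong"
    if R2 < 0.8:
        return "very strong"
    return "perfect"


@dataclass(frozen=True)
class FamilyComparison:
    """r, R² and their bands for one descriptor family of one image pair."""

    family: str
    r: float
    R2: float
    r_band: str
    R2_band: str

    @classmethod
    def from_r(cls, family: str, r: float) -> "FamilyComparison":
        R2 = determination(r)
        return cls(family, r, R2, classify_r(r), classify_R2(R2))


@dataclass(frozen=True)
class ScalarStandardizer:
    """Per-component centering/scaling for the pooled polygon scalars.

    Built from cohort-wide means and SDs of (perimeter, area, shape factor)
    so that the pooled 3-vector correlation is not dominated by the raw
    magnitude differences between the three quantities.
    """

    mean: np.ndarray  # (3,)
    sd: np.ndarray    # (3,)

    @classmethod
    def from_descriptor_sets(cls, sets: list[DescriptorSet]) -> "ScalarStandardizer":
        vals = np.array([[d.perimeter, d.area, d.shape_factor] for d in sets])
        sd = vals.std(axis=0, ddof=1) if len(vals) > 1 else np.ones(3)
        sd = np.where(sd > 0, sd, 1.0)
        return cls(vals.mean(axis=0), sd)

    def __call__(self, d: DescriptorSet) -> np.ndarray:
        raw = np.array([d.perimeter, d.area, d.shape_factor])
        return (raw - self.mean) / self.sd


@dataclass(frozen=True)
class ComparisonResult:
    """Per-family r/R² for one image pair, with interpretive bands."""

    subject_id: str
    modalities: tuple[str, str]
    families: dict[str, FamilyComparison]
    errors: dict[str, str] = field(default_factory=dict)

    def r(self, family: str) -> float:
        return self.families[family].r

    def R2(self, family: str) -> float:
        return self.families[family].R2


def compare_images(a: DescriptorSet, b: DescriptorSet,
                   standardizer: ScalarStandardizer | None = None
                   ) -> ComparisonResult:
    """Compare two descriptor sets family by family.

    A family whose vectors are constant is recorded under ``errors`` rather
    than aborting the remaining families.  ``standardizer`` (cohort scalar
    statistics) is applied to the pooled polygon scalars when given.
    """
    # The moments family is correlated on the log-magnitudes of the seven
    # invariants.  The signed-log descriptor keeps the chirality signs, but
    # the 5th-7th invariants are near-cancelling for flat landmark
    # polygons, so their sign is numerically information-free and a single
    # noise-induced flip would dominate the correlation.  Hu invariants of
    # these polygons have magnitude < 1, so -|signed log10| is their
    # log10 magnitude.
    vectors: dict[str, tuple[np.ndarray, np.ndarray]] = {
        "absolute_distances": (a.absolute_distances, b.absolute_distances),
        "relative_distances": (a.relative_distances, b.relative_distances),
        "moments": (-np.abs(a.moments), -np.abs(b.moments)),
    }
    if standardizer is not None:
        vectors[POOLED_FAMILY] = (standardizer(a), standardizer(b))
    else:
        vectors[POOLED_FAMILY] = (
            np.array([a.perimeter, a.area, a.shape_factor]),
            np.array([b.perimeter, b.area, b.shape_factor]),
        )
    families: dict[str, FamilyComparison] = {}
    errors: dict[str, str] = {}
    for fam, (va, vb) in vectors.items():
        try:
            families[fam] = FamilyComparison.from_r(fam, family_correlation(va, vb))
        except ConstantVectorError as exc:
            errors[fam] = str(exc)
    subject = a.subject_id if a.subject_id == b.subject_id else f"{a.subject_id}|{b.subject_id}"
    return ComparisonResult(subject, (a.modality, b.modality), families, errors)
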