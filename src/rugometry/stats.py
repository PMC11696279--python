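"""Cohort-level statistics: summary cells, the rank test, sample size.

The agreement study aggregates per-subject coefficients into cells shaped
like a clinical summary table — mean ± SD, (min–max), median, (Q1–Q3) —
compares coefficient distributions between impression methods with the
two-sided Wilcoxon–Mann–Whitney test at α = 0.05, and sizes a paired
design with

    n = ceil( (z_{α/2} + z_β)² · σ² / d² )

where σ is the expected SD of the paired differences and d the minimum
detectable difference (same units, typically mm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .exceptions import DegenerateTestError, InvalidInputError, MissingDataError

__all__ = [
    "CellSummary",
    "summarize_cell",
    "summarize_cohort",
    "WMWResult",
    "wmw_test",
    "SampleSizeSpec",
    "paired_sample_size",
]


@dataclass(frozen=True)
class CellSummary:
    """Summary statistics of one table cell (one family/coefficient/pair)."""

    n: int
    mean: float
    sd: float
    min: float
    max: float
    median: float
    q1: float
    q3: float

    def format(self, fmt: str = "{:.4f}") -> str:
        """`mean ± SD (range) median (IQR)` in the table's house style."""
        f = fmt.format
        return (f"{f(self.mean)} ± {f(self.sd)} ({f(self.min)}–{f(self.max)}) "
                f"{f(self.median)} ({f(self.q1)}–{f(self.q3)})")


def summarize_cell(values, label: str = "") -> CellSummary:
    """Mean, SD (n−1), range, median and quartiles (linear interpolation)."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise MissingDataError(f"empty summary cell {label!r}")
    if v.size < 2:
        raise MissingDataError(f"summary cell {label!r} needs >= 2 values, got {v.size}")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return CellSummary(
        n=int(v.size), mean=float(v.mean()), sd=float(v.std(ddof=1)),
        min=float(v.min()), max=float(v.max()),
        median=float(med), q1=float(q1), q3=float(q3),
    )


def summarize_cohort(groups: dict) -> dict:
    """Summarize many cells at once.

    ``groups`` maps a cell key (e.g. ``(family, coefficient, pair)``) to its
    values; returns the same keys mapped to :class:`CellSummary`.  Order of
    values within a cell does not matter.
    """
    return {key: summarize_cell(vals, label=str(key)) for key, vals in groups.items()}


@dataclass(frozen=True)
class WMWResult:
    """Wilcoxon–Mann–Whitney outcome at the study's α = 0.05."""

    U: float
    p_value: float
    significant: bool
    method: str  # "exact" or "asymptotic"


def wmw_test(group_a, group_b, alpha: float = 0.05, method: str = "auto") -> WMWResult:
    """Two-sided Mann–Whitney U test between two value groups.

    With ``method="auto"``, uses exact enumeration of the U distribution
    when both groups have fewer than 8 values and there are no ties, and
    the tie-corrected normal approximation (with continuity correction)
    otherwise.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 3 or b.size < 3:
        raise InvalidInputError("each group needs >= 3 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        raise DegenerateTestError("all values tied across both groups")
    has_ties = len(np.unique(pooled)) < pooled.size
    if method == "auto":
        method = "exact" if (a.size < 8 and b.size < 8 and not has_ties) else "asymptotic"
    if method not in ("exact", "asymptotic"):
        raise InvalidInputError(f"unknown method {method!r}")
    res = _sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                            use_continuity=True)
    p = float(min(res.pvalue, 1.0))
    return WMWResult(U=float(res.statistic), p_value=p,
                     significant=bool(p < alpha), method=method)


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs of the paired-design sample-size formula."""

    alpha: float = 0.05   # two-sided significance level
    power: float = 0.90   # 1 - beta
    sigma: float = 0.1    # expected SD of paired differences (mm)
    delta: float = 0.05   # minimum detectable difference (mm)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise InvalidInputError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 < self.power < 1:
            raise InvalidInputError(f"power must be in (0,1), got {self.power}")
        if self.sigma <= 0 or self.delta <= 0:
            raise InvalidInputError("sigma and delta must be positive")


def paired_sample_size(spec: SampleSizeSpec, rounded_z: bool = False) -> int:
    """n = ceil((z_{α/2} + z_β)² σ² / d²), two-sided normal quantiles.

    ``rounded_z=True`` uses the quantiles rounded to two decimals (the
    convention of printed tables, e.g. 1.96 and 1.28); the default computes
    them exactly from the normal inverse CDF.
    """
    z_a = float(_sps.norm.ppf(1.0 - spec.alpha / 2.0))
    z_b = float(_sps.norm.ppf(spec.power))
    if rounded_z:
        z_a, z_b = round(z_a, 2), round(z_b, 2)
    n = (z_a + z_b) ** 2 * spec.sigma**2 / spec.delta**2
    return int(math.ceil(n - 1e-12))  # guard float fuzz at integer n
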