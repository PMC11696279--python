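"""Cross-modality agreement study as a model/results pair.

:class:`CrossModalityAgreement` is built from the landmark sets of a cohort
(each subject recorded as clinical photograph, plaster model and/or
intraoral scan) and, like a statsmodels model, does all the work in
``fit()``, which returns :class:`AgreementResults`:

* per subject and modality pair, descriptors are computed from each record
  (in its own metric frame by default; optionally after least-squares
  similarity superimposition of the moving set on the fixed set) and each
  family is matched via Pearson r and R² = r²;
* vector families (absolute distances, relative distances, moments, and
  the pooled polygon scalars) yield one coefficient per subject, which are
  aggregated into mean ± SD (range) median (IQR) cells;
* the scalar families (perimeters, areas, shape factors) are single numbers
  per image, so their per-pair coefficient is the correlation of the scalar
  across cohort subjects; its spread columns come from leave-one-out
  jackknife replicates of that correlation;
* coefficient distributions of the photograph-vs-plaster and
  photograph-vs-scan comparisons are compared with the two-sided
  Wilcoxon–Mann–Whitney test at α = 0.05 — the study's headline question of
  whether the two impression methods are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptors import DescriptorSet, compute_descriptors
from .exceptions import InvalidInputError
from .landmarks import MODALITIES, LandmarkSet, align_similarity
from .matching import (
    ComparisonResult,
    FamilyComparison,
    ScalarStandardizer,
    compare_images,
    family_correlation,
)
from .stats import CellSummary, WMWResult, summarize_cell, wmw_test

__all__ = ["CrossModalityAgreement", "AgreementResults"]

#: per-subject (vector) families, in report order
PER_SUBJECT_FAMILIES = ("absolute_distances", "relative_distances",
                        "polygon_scalars", "moments")
#: across-cohort scalar families: report label -> DescriptorSet attribute
SCALAR_FAMILIES = {"perimeters": "perimeter", "areas": "area",
                   "shape_factors": "shape_factor"}
#: the six families of the study report, in its row order
REPORT_FAMILIES = ("absolute_distances", "relative_distances", "perimeters",
                   "areas", "shape_factors", "moments")


def _pair_label(a: str, b: str) -> str:
    return f"{a}-{b}"


class CrossModalityAgreement:
    """Agreement model over a cohort of per-subject modality landmark sets.

    Parameters
    ----------
    landmark_sets
        All landmark sets of the cohort; subjects are grouped by
        ``subject_id`` and must each carry at least two distinct modalities.
    align
        Superimpose the moving set on the fixed set per pair before
        computing descriptors.  Default False: each record is measured in
        its own metric frame, as the comparison software measured each
        image independently; superimposition in the source protocol served
        landmark placement, not measurement.  Set True when coordinate
        frames are not metrically comparable (e.g. photographs in pixel
        units without a scale reference).
    """

    def __init__(self, landmark_sets: list[LandmarkSet], align: bool = False):
        if not landmark_sets:
            raise InvalidInputError("no landmark sets supplied")
        self.align = bool(align)
        self.subjects: dict[str, dict[str, LandmarkSet]] = {}
        for ls in landmark_sets:
            if ls.modality not in MODALITIES:
                raise InvalidInputError(
                    f"landmark set {ls.subject_id!r} has non-study modality "
                    f"{ls.modality!r}")
            self.subjects.setdefault(ls.subject_id, {})[ls.modality] = ls
        modalities = [m for m in MODALITIES
                      if all(m in d for d in self.subjects.values())]
        if len(modalities) < 2:
            raise InvalidInputError(
                "need >= 2 modalities present for every subject")
        self.modalities = tuple(modalities)
        self.pairs = tuple(
            (modalities[i], modalities[j])
            for i in range(len(modalities)) for j in range(i + 1, len(modalities)))
        self.cohort = None  # set by from_simulation

    # ---------------------------------------------------------- constructors
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, align: bool = False
                       ) -> "CrossModalityAgreement":
        """Build from a tidy landmark table (subject_id, modality, landmark_index, x, y)."""
        from .io import frame_to_landmark_sets

        return cls(frame_to_landmark_sets(df), align=align)

    @classmethod
    def from_file(cls, path, fmt: str = "auto", align: bool = False
                  ) -> "CrossModalityAgreement":
        """Build from a delimited landmark file or a TPS file."""
        from .io import read_landmarks, read_tps

        if fmt == "auto":
            fmt = "tps" if str(path).lower().endswith(".tps") else "table"
        sets = read_tps(path) if fmt == "tps" else read_landmarks(path)
        return cls(sets, align=align)

    @classmethod
    def from_simulation(cls, n_subjects: int = 19, master_seed: int = 0,
                        modality_models=None, base_spec=None, align: bool = False
                        ) -> "CrossModalityAgreement":
        """Build from a freshly generated synthetic cohort."""
        from .simulate import generate_cohort

        cohort = generate_cohort(n_subjects=n_subjects,
                                 modality_models=modality_models,
                                 master_seed=master_seed, base_spec=base_spec)
        model = cls(cohort.landmark_sets(), align=align)
        model.cohort = cohort
        return model

    # ----------------------------------------------------------------- fit
    def fit(self) -> "AgreementResults":
        # descriptors of every record in its own frame (used for the cohort
        # scalar standardization)
        all_desc = [compute_descriptors(ls)
                    for d in self.subjects.values() for ls in d.values()]
        standardizer = ScalarStandardizer.from_descriptor_sets(all_desc)

        comparisons: list[ComparisonResult] = []
        coeff_rows: list[dict] = []
        scalar_vectors: dict[str, dict[str, list[float]]] = {}
        for fixed_m, moving_m in self.pairs:
            pair = _pair_label(fixed_m, moving_m)
            scalar_vectors[pair] = {"fixed_perimeter": [], "moving_perimeter": [],
                                    "fixed_area": [], "moving_area": [],
                                    "fixed_shape_factor": [], "moving_shape_factor": []}
        for sid in sorted(self.subjects):
            records = self.subjects[sid]
            for fixed_m, moving_m in self.pairs:
                pair = _pair_label(fixed_m, moving_m)
                fixed_ls = records[fixed_m]
                moving_ls = records[moving_m]
                if self.align:
                    moving_ls, _ = align_similarity(moving_ls, fixed_ls)
                d_fixed = compute_descriptors(fixed_ls)
                d_moving = compute_descriptors(moving_ls)
                cmp_ = compare_images(d_fixed, d_moving, standardizer=standardizer)
                comparisons.append(cmp_)
                for fam, fc in cmp_.families.items():
                    coeff_rows.append({"subject_id": sid, "pair": pair,
                                       "family": fam, "r": fc.r, "R2": fc.R2,
                                       "r_band": fc.r_band, "R2_band": fc.R2_band})
                sv = scalar_vectors[pair]
                for label, attr in SCALAR_FAMILIES.items():
                    sv[f"fixed_{attr}"].append(getattr(d_fixed, attr))
                    sv[f"moving_{attr}"].append(getattr(d_moving, attr))

        coefficients = pd.DataFrame(coeff_rows)

        # across-cohort coefficients for the scalar families, with jackknife
        scalar_rows: list[dict] = []
        jackknife: dict[tuple[str, str], np.ndarray] = {}
        for fixed_m, moving_m in self.pairs:
            pair = _pair_label(fixed_m, moving_m)
            sv = scalar_vectors[pair]
            for label, attr in SCALAR_FAMILIES.items():
                a = np.asarray(sv[f"fixed_{attr}"])
                b = np.asarray(sv[f"moving_{attr}"])
                fc = FamilyComparison.from_r(label, family_correlation(a, b))
                scalar_rows.append({"pair": pair, "family": label, "r": fc.r,
                                    "R2": fc.R2, "r_band": fc.r_band,
                                    "R2_band": fc.R2_band, "n_subjects": len(a)})
                if len(a) >= 4:
                    reps = np.array([
                        family_correlation(np.delete(a, i), np.delete(b, i))
                        for i in range(len(a))])
                    jackknife[(pair, label)] = reps
        scalar_coefficients = pd.DataFrame(scalar_rows)

        return AgreementResults(self, comparisons, coefficients,
                                scalar_coefficients, jackknife)


@dataclass
class AgreementResults:
    """Fitted agreement study: coefficients, summary cells and rank tests."""

    model: CrossModalityAgreement
    comparisons: list[ComparisonResult]
    coefficients: pd.DataFrame          # per-subject r/R2, vector families
    scalar_coefficients: pd.DataFrame   # across-cohort r/R2, scalar families
    _jackknife: dict

    def __post_init__(self) -> None:
        self.pair_labels = tuple(_pair_label(a, b) for a, b in self.model.pairs)
        self._cells: dict[tuple[str, str, str], CellSummary] = {}
        for pair in self.pair_labels:
            for fam in PER_SUBJECT_FAMILIES:
                sel = self.coefficients.query("pair == @pair and family == @fam")
                if len(sel) >= 2:
                    for coeff in ("r", "R2"):
                        self._cells[(fam, coeff, pair)] = summarize_cell(
                            sel[coeff], label=f"{fam}/{coeff}/{pair}")
            for fam in SCALAR_FAMILIES:
                reps = self._jackknife.get((pair, fam))
                if reps is not None:
                    self._cells[(fam, "r", pair)] = summarize_cell(
                        reps, label=f"{fam}/r/{pair}")
                    self._cells[(fam, "R2", pair)] = summarize_cell(
                        reps**2, label=f"{fam}/R2/{pair}")
        self.wmw_: dict[str, WMWResult] = {}
        self.wmw_by_family_: dict[tuple[str, str], WMWResult] = {}
        ref_pairs = (_pair_label("photo", "plaster"), _pair_label("photo", "scan"))
        if all(p in self.pair_labels for p in ref_pairs):
            df = self.coefficients
            ga = df[df["pair"] == ref_pairs[0]]
            gb = df[df["pair"] == ref_pairs[1]]
            for coeff in ("r", "R2"):
                self.wmw_[coeff] = wmw_test(ga[coeff], gb[coeff])
                for fam in PER_SUBJECT_FAMILIES:
                    self.wmw_by_family_[(fam, coeff)] = wmw_test(
                        ga.loc[ga["family"] == fam, coeff],
                        gb.loc[gb["family"] == fam, coeff])

    # ------------------------------------------------------------- accessors
    def cell(self, family: str, coefficient: str, pair: str) -> CellSummary:
        """Summary cell for one (family, r/R2, modality-pair) combination."""
        return self._cells[(family, coefficient, pair)]

    def mean_r(self, family: str, pair: str) -> float:
        """Cohort mean correlation for one family and modality pair.

        Vector families: mean of per-subject r.  Scalar families: the
        across-cohort correlation itself.
        """
        if family in SCALAR_FAMILIES:
            sel = self.scalar_coefficients.query("pair == @pair and family == @family")
            return float(sel["r"].iloc[0])
        return self._cells[(family, "r", pair)].mean

    def family_mean_r(self, pair: str) -> dict[str, float]:
        """Mean r of each of the six report families for one pair."""
        return {fam: self.mean_r(fam, pair) for fam in REPORT_FAMILIES}

    @property
    def table(self) -> pd.DataFrame:
        """Study-report-shaped table: families x coefficients vs pairs."""
        rows = []
        for fam in REPORT_FAMILIES:
            for coeff in ("r", "R2"):
                row = {"family": fam, "coefficient": coeff}
                for pair in self.pair_labels:
                    key = (fam, coeff, pair)
                    row[pair] = self._cells[key].format() if key in self._cells else ""
                rows.append(row)
        return pd.DataFrame(rows)

    # --------------------------------------------------------------- report
    def summary(self) -> str:
        """Plain-text study report in the house style of the field."""
        lines = ["Cross-modality rugae agreement study",
                 "=" * 72,
                 f"subjects: {len(self.model.subjects)}    "
                 f"modalities: {', '.join(self.model.modalities)}    "
                 f"aligned: {self.model.align}",
                 ""]
        for pair in self.pair_labels:
            lines.append(f"comparison {pair}  [mean ± SD (range) median (IQR)]")
            for fam in REPORT_FAMILIES:
                for coeff in ("r", "R2"):
                    key = (fam, coeff, pair)
                    if key in self._cells:
                        lines.append(f"  {fam:<20s} {coeff:<3s} "
                                     f"{self._cells[key].format()}")
            lines.append("")
        if self.wmw_:
            lines.append("Wilcoxon-Mann-Whitney, photo-plaster vs photo-scan "
                         "coefficient distributions:")
            for coeff, res in self.wmw_.items():
                verdict = "significant" if res.significant else "not significant"
                lines.append(f"  {coeff:<3s} U={res.U:.1f}  p={res.p_value:.4f}  "
                             f"({verdict} at 0.05, {res.method})")
        return "\n".join(lines)

    def plot_coefficients(self, coefficient: str = "r", ax=None):
        """Box plot of per-subject coefficients by family and modality pair."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 4))
        data, labels = [], []
        for fam in PER_SUBJECT_FAMILIES:
            for pair in self.pair_labels:
                sel = self.coefficients.query("pair == @pair and family == @fam")
                data.append(sel[coefficient].to_numpy())
                labels.append(f"{fam}\n{pair}")
        ax.boxplot(data, tick_labels=labels)
        ax.set_ylabel(coefficient)
        ax.tick_params(axis="x", labelsize=7)
        return ax
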