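# Methods

This note documents the models, numerical choices and known limitations of
`rugometry`. It is written for users who need to know exactly what the
pipeline computes and what passing tests do and do not demonstrate.

## Geometry

Triangle areas use the homogeneous-coordinate determinant,
`area = ½·|det[[xᵢ,yᵢ,1],[xⱼ,yⱼ,1],[xₖ,yₖ,1]]|`; polygon areas come from a
fan triangulation into signed determinant triangles, which equals the
shoelace value on simple polygons. Before any polygon measurement the six
landmarks are put into canonical order — sorted by angle about their
centroid, ties broken by radius — which guarantees a simple (star-shaped)
boundary even though the protocol's landmark sequence zig-zags between the
two rugae. The original protocol order is preserved in the `LandmarkSet`
for labelling. An area below `1e-12 ×` (bounding-box diagonal)² is treated
as exactly zero; a zero-perimeter figure has no defined compactness and
raises. Coordinates are unit-agnostic and the image convention (y growing
downward/posteriorly) is accepted throughout; every reported quantity is
invariant to that choice except the sign of the seventh Hu invariant,
which is a chirality and flips under any reflection.

## Landmark protocol

The five reference lines are infinite lines along the mid-sagittal
direction, one through the interincisal point and four through the incisor
collar points. When a line crosses a curved ruga more than once, the
anterior-most crossing (smallest coordinate along the sagittal direction)
is taken, because rugae are read from the incisive papilla backward; this
disambiguation rule is a package choice, not part of the source protocol.
Two landmark configurations can be superimposed by closed-form
least-squares similarity alignment (rotation, isotropic scale,
translation; reflections are excluded as anatomically meaningless). The
alignment replaces the manual image-superimposition step of clinical
practice with a reproducible, operator-free operation.

By default the agreement pipeline does **not** align records before
measuring them: each record is measured in its own metric frame, exactly
as comparison software measures each uploaded image independently;
superimposition in the clinical workflow serves landmark placement, not
measurement. `align=True` is available for records whose coordinate
frames are not metrically comparable (e.g. photographs in pixel units
without a scale reference). Note that alignment is not neutral for the
scalar families: its scale fit absorbs part of any anteroposterior
foreshortening difference and thereby changes the area family's noise
budget.

## Descriptor families

- Absolute distances: the 15 pairwise distances in fixed lexicographic
  pair order (1,2), (1,3), …, (5,6).
- Relative distances: the same vector divided by its maximum entry. Any
  per-record scalar normalizer leaves Pearson r unchanged, so within a
  record pair this family correlates identically to the absolute family;
  it differs in the values themselves (scale-free, max exactly 1), which
  is what matters for serialization and cross-study comparability. The
  choice of the maximum as normalizer is a package decision.
- Polygon scalars: perimeter, area and the shape factor `A/P²` of the
  canonical landmark hexagon. The shape factor is the single compactness
  index; no further shape factors are computed.
- Moments: Hu's seven invariants of the *filled* canonical polygon.
  Raw moments `m_pq = ∬ x^p y^q dA` (p+q ≤ 3) are integrated exactly over
  the polygon by mapping each fan triangle to the unit simplex — no
  rasterization, hence no resolution artifacts. Central and normalized
  moments and the seven invariants follow the standard formulas. Because
  the invariants span many orders of magnitude, the stored descriptor is
  the signed log, `sign(h)·log₁₀|h|` (exact zeros map to 0).

### Moment matching uses log-magnitudes

For flat six-landmark hexagons the 5th–7th Hu invariants are
near-cancelling differences of third-order terms: their magnitude is two
to four orders below the terms that form them, so modality-level noise can
flip their *sign* while barely moving their magnitude. A single sign flip
moves a signed-log component across the whole dynamic range and destroys
the family correlation for that subject. The pairwise comparison therefore
correlates the log-magnitudes `log₁₀|h_k|` of the seven invariants (for
these polygons |h| < 1, so the log-magnitude is `−|signed log|`). The
signed descriptor is kept — the seventh invariant's sign still detects
reflection — but the sign carries no stable identity information for this
landmark geometry and is excluded from the correlation.

## Matching and bands

r is the plain Pearson product-moment correlation on raw descriptor values
(no rank transform), and R² = r² exactly. Band boundaries follow the
operation definitions: r = 0.3 and r = 0.7 belong to "moderate"; R²
boundaries 0.2/0.4/0.6/0.8 belong to the upper band ([0.2, 0.4) moderate,
…, [0.8, 1.0] perfect); R² = 0 is "none". These tie rules are documented
package decisions, since strict inequalities leave boundary values
undefined in the source definitions.

The scalar families cannot yield a correlation from a single record pair.
Two readings are implemented:

- within a pair, the three scalars are pooled into one 3-vector per
  record (standardized per component with cohort-wide means and SDs when
  available) and correlated — the `polygon_scalars` per-subject family;
- for study-shaped reports, each scalar is correlated *across cohort
  subjects*, giving one coefficient per family and modality pair — the
  only reading under which per-family area/perimeter coefficients are
  computable at all. The spread columns (SD, range, IQR) for these
  across-cohort coefficients come from leave-one-out jackknife
  replicates, a standard way to attach spread to a single statistic; they
  quantify estimator stability, not between-subject variation.

The Wilcoxon–Mann–Whitney comparison between the photo-vs-plaster and
photo-vs-scan coefficient distributions pools only genuinely per-subject
coefficients (absolute distances, relative distances, pooled polygon
scalars, moments). The two groups share the photograph and are therefore
correlated; the test is reported exactly as the field reports it, as a
two-sided location comparison at α = 0.05.

## Cohort statistics

Summary cells use the sample SD (n−1 denominator) and
linear-interpolation quartiles; the IQR parenthetical is Q1–Q3. The
Mann–Whitney U test uses exact enumeration when both groups have fewer
than 8 tie-free values and the tie-corrected normal approximation with
continuity correction otherwise (both branches are scipy's; an exhaustive
permutation oracle validates them in the tests). The paired sample size
uses exact normal quantiles by default; `rounded_z=True` reproduces the
printed-table convention (1.96, 1.28), giving 42 instead of 43 for
α = 0.05, power 0.90, σ = 0.1 mm, d = 0.05 mm. Both values follow from
the formula; neither is tuned.

## Synthetic palates and modality models

No landmark data are deposited for this kind of study, so the study
conditions are defined by a generator with full ground truth.

**Palate.** In mm, interincisal point at the origin, y growing
posteriorly. Collar offsets are fixed fractions of the arch width
(central incisor ≈ 8.5 mm, lateral ≈ 6.5 mm wide). Ruga *i* is a polyline
`y(x) = y₀ + (i−1)·spacing + bow·(2x/w)² + damp(x)·[A·cos(2πfx) +
asymmetry·B·sin(2πgx+φ)]` with per-ruga parameters drawn from the
subject's seeded stream; `damp` fades waviness toward the arch edges.
With `asymmetry = 0` the curve is even in x and left/right landmark pairs
are mirror images. The polyline sampling grid contains the exact
reference-line abscissae, so stored ground-truth landmarks are exact
intersections (recovered by the extractor to < 1e-9). Between-subject
anatomy varies as: arch width 32 ± 2.5 mm, ruga spacing 5 ± 0.6 mm, wave
amplitude 1.5 ± 0.55 mm, frequency 0.14 ± 0.03 cycles/mm, bow 1.5 ± 1.0
mm, asymmetry uniform on [0.5, 1].

**Modalities.** All three records are treated as 2-D projections of a
domed palate. Each record applies, in order: curve smoothing (moving
average; plaster 0.35 mm window, scan 0.25 mm — loss of fine ridge
detail), isotropic scale bias (plaster 0.98, alginate/plaster setting
shrinkage), anteroposterior foreshortening (y compressed by a factor
1 + ε, ε ~ N(0, 0.18), clipped to ±0.4 — the projection axis varies per
acquisition), a small projective warp (photo only, jitter 0.003), and
landmark-scale noise of 0.28 mm. The noise is realized as a smooth
low-frequency vertical field along each ruga plus independent noise on the
frame points (which shifts the reference lines transversely and moves
landmarks along the ruga — the dominant error of manual line placement).
Literally independent noise on every polyline vertex is *not* used: it
makes line–ruga crossings multivalued and biases the anterior-most rule.

These magnitudes are configuration values of a synthetic model, chosen
once so that cross-modality coefficients land in the bands real
photo/cast/scan rugoscopy reports — moments and distance families near 1,
perimeters strong, areas lowest (foreshortening hits the area directly,
while the width-dominated perimeter and all scale-free families largely
escape it) — and so that the two impression methods are statistically
equivalent. They are not measurements of any imaging system.

**Reproducibility.** Every operation is a pure function of its inputs and
a seed; cohorts use spawned seed sequences per subject, so a cohort is
reproducible and a subject's record does not depend on cohort ordering.

## What the synthetic study does and does not show

Passing tests demonstrate that the pipeline is internally correct
(formulas, invariances, statistics) and that under the stated synthetic
conditions it reproduces the qualitative structure of real
cross-modality rugoscopy: family ordering (moments most robust, areas
least), strong agreement bands, and no cast-vs-scan difference. They do
not validate the modality models against any physical imaging system,
do not cover rugae segmentation or landmark placement by human operators,
and say nothing about identification performance in populations — the
generator produces plausible geometry, not anatomy. Because the
across-cohort scalar coefficients are single correlations estimated from
n subjects, their sampling noise at n = 200 is roughly ±0.04; the
areas-vs-shape-factors ordering is therefore asserted on means pooled
over the three modality pairs.

## Problem sizes

The test suite runs the full study at 200 synthetic subjects (the package's
chosen Monte Carlo size for stable family ordering) and the end-to-end
report at 19 subjects, the size of a typical single-center cohort; both
complete in seconds.

## Known limitations

- The landmark hexagon is wide and flat, so the seventh Hu invariant is
  intrinsically ill-conditioned (see above); identity information lives in
  the magnitudes.
- Relative distances duplicate absolute distances under Pearson matching
  (any per-record scalar normalizer cancels); the family is kept for its
  scale-free values, not for extra discriminative power.
- The similarity alignment assumes corresponding landmarks; it cannot
  recover from mislabeled landmark order.
- Curves are planar; the z-relief of rugae and 3-D mesh processing are out
  of scope.
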