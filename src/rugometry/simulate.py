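"""Synthetic palates and modality-distorted replicates with known ground truth.

No landmark data are deposited with the study this package emulates, so the
agreement analysis runs on synthetic cohorts: each subject is a randomly
drawn palate — an incisor frame plus transverse, wavy, individually
distinct rugae — recorded three times (clinical photograph, plaster model,
intraoral scan) through modality models that add realistic geometric
distortion while sharing the one underlying rugae pattern.

**Palate model.**  Working in mm with the image convention (y grows
posteriorly), the interincisal point sits at the origin and the collar
points of the four upper incisors at transverse offsets proportional to the
arch width.  Ruga *i* is a polyline sampled from

    y(x) = y0 + (i-1)·spacing + bow·(2x/w)² + damp(x)·[ A·cos(2πf x)
           + asymmetry · B·sin(2πg x + φ) ]

where damp(x) = exp(-(x/(0.55·w/2))²) fades the waviness toward the arch
edges; per-ruga amplitudes, frequencies, bows and phases are drawn from the
subject's seeded stream, so patterns are individually distinct.  With
``asymmetry = 0`` the curve is an even function of x and left/right
landmark pairs are mirror images.

**Modality models.**  The photograph applies a small projective warp
(perspective of a hand-held camera); the plaster cast applies an isotropic
shrinkage factor (alginate/plaster setting) and curve smoothing (loss of
fine ridge detail); the scan applies lighter smoothing.  All three add
landmark-scale geometric noise, realized as a smooth low-frequency random
field along each ruga plus independent noise on the frame points — smooth
because impression and optical distortions deform curves coherently, not
point by point.  Default magnitudes are calibrated so that cross-modality
coefficients land in the reported bands of real photo/cast/scan rugoscopy;
they are synthetic configuration values, not measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import GenerationError, InvalidInputError
from .geometry import Point2D
from .landmarks import (
    MODALITIES,
    IncisorFrame,
    LandmarkSet,
    RugaCurve,
    extract_landmarks,
)

__all__ = [
    "PalateSpec",
    "ModalityModel",
    "SyntheticPalate",
    "SubjectRecord",
    "Cohort",
    "default_modality_models",
    "generate_palate",
    "apply_modality",
    "generate_cohort",
]

#: collar transverse offsets as a fraction of arch width (FDI 1.1/2.1
#: centrals, 1.2/2.2 laterals; central incisor ~8.5 mm wide, lateral ~6.5 mm)
_CENTRAL_FRAC = 4.25 / 32.0
_LATERAL_FRAC = 11.75 / 32.0
_N_CURVE_SAMPLES = 97
_FIRST_RUGA_OFFSET = 4.0  # mm behind the interincisal point

# landmark-noise realization: split between the smooth vertical field along
# each ruga and the reference-frame point noise (transverse line placement)
_FIELD_NOISE_FACTOR = 0.5
_FRAME_NOISE_FACTOR = 1.5

# between-subject anatomical variation (SDs around the base spec)
_WIDTH_SD = 2.5       # mm
_SPACING_SD = 0.6     # mm
_AMP_SD = 0.55        # mm
_FREQ_SD = 0.03       # cycles/mm
_RUGA_Y_JITTER = 0.05  # fraction of ruga spacing, per ruga
_BOW_SD = 1.0         # mm


@dataclass(frozen=True)
class PalateSpec:
    """Parameters of one synthetic palate (lengths in mm)."""

    seed: int = 0
    n_rugae: int = 4
    arch_width: float = 32.0
    ruga_wave_amplitude: float = 1.5
    ruga_wave_frequency: float = 0.14  # cycles per mm
    ruga_spacing: float = 5.0
    asymmetry: float = 0.7

    def __post_init__(self) -> None:
        if self.n_rugae < 2:
            raise InvalidInputError("need at least 2 rugae for the landmark protocol")
        for name in ("arch_width", "ruga_wave_amplitude", "ruga_wave_frequency",
                     "ruga_spacing"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise InvalidInputError("asymmetry must lie in [0, 1]")


@dataclass(frozen=True)
class ModalityModel:
    """Geometric distortion model of one recording modality (lengths in mm)."""

    kind: str
    landmark_noise_sd: float = 0.2
    scale_bias: float = 1.0
    projective_jitter: float = 0.0  # photo only
    smoothing_window: float = 0.0   # cast/scan curve smoothing
    foreshortening_sd: float = 0.0  # per-record anteroposterior projection jitter

    def __post_init__(self) -> None:
        if self.kind not in MODALITIES:
            raise InvalidInputError(f"kind must be one of {MODALITIES}")
        if self.landmark_noise_sd < 0:
            raise InvalidInputError("landmark_noise_sd must be >= 0")
        if self.scale_bias <= 0:
            raise InvalidInputError("scale_bias must be > 0")


def default_modality_models() -> dict[str, ModalityModel]:
    """Calibrated default models for the three recording modalities."""
    return {
        "photo": ModalityModel("photo", landmark_noise_sd=0.28,
                               scale_bias=1.0, projective_jitter=0.003,
                               foreshortening_sd=0.18),
        "plaster": ModalityModel("plaster", landmark_noise_sd=0.28,
                                 scale_bias=0.98, smoothing_window=0.35,
                                 foreshortening_sd=0.18),
        "scan": ModalityModel("scan", landmark_noise_sd=0.28,
                              scale_bias=1.0, smoothing_window=0.25,
                              foreshortening_sd=0.18),
    }


@dataclass(frozen=True)
class SyntheticPalate:
    """A generated palate with its exact ground-truth landmarks."""

    frame: IncisorFrame
    rugae: tuple[RugaCurve, ...]
    true_landmarks: LandmarkSet
    spec: PalateSpec


def _ruga_params(rng: np.random.Generator, spec: PalateSpec, n: int) -> list[dict]:
    """Per-ruga shape parameters drawn from the subject stream."""
    out = []
    for _ in range(n):
        out.append(dict(
            amp=spec.ruga_wave_amplitude * float(rng.uniform(0.7, 1.3)),
            freq=spec.ruga_wave_frequency * float(rng.uniform(0.8, 1.2)),
            amp_a=spec.ruga_wave_amplitude * float(rng.uniform(0.8, 1.5)),
            freq_a=spec.ruga_wave_frequency * float(rng.uniform(0.3, 0.9)),
            phase_a=float(rng.uniform(0.0, 2.0 * math.pi)),
            bow=float(rng.normal(1.5, _BOW_SD)),
            y_jitter=float(rng.normal(0.0, _RUGA_Y_JITTER * spec.ruga_spacing)),
        ))
    return out


def _ruga_y(x: np.ndarray, base_y: float, p: dict, spec: PalateSpec) -> np.ndarray:
    half = spec.arch_width / 2.0
    damp = np.exp(-((x / (0.55 * half)) ** 2))
    sym = p["amp"] * np.cos(2.0 * math.pi * p["freq"] * x)
    asym = spec.asymmetry * p["amp_a"] * np.sin(
        2.0 * math.pi * p["freq_a"] * x + p["phase_a"])
    return base_y + p["bow"] * (x / half) ** 2 + damp * (sym + asym)


def _line_xs(spec: PalateSpec) -> np.ndarray:
    """Transverse positions of the five reference lines (patient left = +x)."""
    c1 = _CENTRAL_FRAC * spec.arch_width
    c2 = _LATERAL_FRAC * spec.arch_width
    return np.array([-c2, -c1, 0.0, c1, c2])


def generate_palate(spec: PalateSpec, subject_id: str = "S0") -> SyntheticPalate:
    """Deterministically generate one palate from its spec.

    The sampling grid of every ruga polyline contains the exact reference
    line abscissae, so the stored ground-truth landmarks are exact
    line-ruga intersections.
    """
    rng = np.random.default_rng(spec.seed)
    half = spec.arch_width / 2.0
    xs_lines = _line_xs(spec)
    if np.any(np.abs(xs_lines) >= half):
        raise GenerationError(
            f"reference lines at |x|={np.abs(xs_lines).max():.2f} fall outside the "
            f"ruga span ±{half:.2f}; no line-ruga intersections possible")
    grid = np.unique(np.concatenate([np.linspace(-half, half, _N_CURVE_SAMPLES),
                                     xs_lines]))
    params = _ruga_params(rng, spec, spec.n_rugae)
    rugae = []
    for i, p in enumerate(params, start=1):
        base = _FIRST_RUGA_OFFSET + (i - 1) * spec.ruga_spacing + p["y_jitter"]
        ys = _ruga_y(grid, base, p, spec)
        rugae.append(RugaCurve(
            tuple(Point2D(float(x), float(y)) for x, y in zip(grid, ys)), index=i))
    c1 = _CENTRAL_FRAC * spec.arch_width
    c2 = _LATERAL_FRAC * spec.arch_width
    collar_y_c = -1.0
    collar_y_l = -0.5
    frame = IncisorFrame(
        collar_11=Point2D(-c1, collar_y_c), collar_12=Point2D(-c2, collar_y_l),
        collar_21=Point2D(c1, collar_y_c), collar_22=Point2D(c2, collar_y_l),
        interincisal=Point2D(0.0, 0.0), sagittal_dir=(0.0, 1.0),
    )

    def y_of(ruga_i: int, x: float) -> float:
        p = params[ruga_i - 1]
        base = _FIRST_RUGA_OFFSET + (ruga_i - 1) * spec.ruga_spacing + p["y_jitter"]
        return float(_ruga_y(np.array([x]), base, p, spec)[0])

    # protocol sequence: 2.1xR1, 2.2xR1, 1.1xR1, 1.2xR1, 1.1xR2, 2.2xR2
    truth = LandmarkSet((
        Point2D(c1, y_of(1, c1)), Point2D(c2, y_of(1, c2)),
        Point2D(-c1, y_of(1, -c1)), Point2D(-c2, y_of(1, -c2)),
        Point2D(-c1, y_of(2, -c1)), Point2D(c2, y_of(2, c2)),
    ), modality="truth", subject_id=subject_id)
    return SyntheticPalate(frame, tuple(rugae), truth, spec)


def _smooth(ys: np.ndarray, window_pts: int) -> np.ndarray:
    if window_pts <= 1:
        return ys
    k = window_pts if window_pts % 2 == 1 else window_pts + 1
    pad = k // 2
    padded = np.concatenate([ys[pad:0:-1], ys, ys[-2:-2 - pad:-1]])
    kernel = np.ones(k) / k
    return np.convolve(padded, kernel, mode="valid")


def _smooth_noise_field(rng: np.random.Generator, x: np.ndarray, sd: float,
                        extent: float) -> np.ndarray:
    """Low-frequency random field with pointwise SD ~ sd over [-extent, extent]."""
    if sd == 0.0:
        return np.zeros_like(x)
    n_modes = 3
    coeffs = rng.normal(0.0, sd / math.sqrt(n_modes), size=(n_modes, 2))
    out = np.zeros_like(x, dtype=float)
    for m in range(1, n_modes + 1):
        w = math.pi * m * (x / extent)
        out += coeffs[m - 1, 0] * np.cos(w) + coeffs[m - 1, 1] * np.sin(w)
    return out


def _project(xy: np.ndarray, H: np.ndarray) -> np.ndarray:
    homo = np.column_stack([xy, np.ones(len(xy))]) @ H.T
    return homo[:, :2] / homo[:, 2:3]


def apply_modality(palate: SyntheticPalate, model: ModalityModel,
                   seed: int | np.random.SeedSequence = 0
                   ) -> tuple[IncisorFrame, tuple[RugaCurve, ...]]:
    """Distort a palate's geometry as one recording modality would.

    Deterministic given ``seed``.  Order of operations: curve smoothing,
    isotropic scale bias about the interincisal point, projective warp
    (photo), then the smooth landmark-scale noise field on each ruga plus
    independent noise on the frame points.  With all distortion parameters
    at their identity values the output equals the input geometry.
    """
    rng = np.random.default_rng(seed)
    spec = palate.spec
    half = spec.arch_width / 2.0
    origin = palate.frame.interincisal.as_array()

    curves = [r.as_array() for r in palate.rugae]
    frame_pts = np.array([p.as_array() for p in (
        palate.frame.collar_11, palate.frame.collar_12,
        palate.frame.collar_21, palate.frame.collar_22,
        palate.frame.interincisal)])

    if model.smoothing_window > 0:
        for c in curves:
            dx = np.median(np.abs(np.diff(c[:, 0]))) or 1.0
            k = max(1, int(round(model.smoothing_window / dx)))
            c[:, 1] = _smooth(c[:, 1], k)

    if model.scale_bias != 1.0:
        curves = [origin + model.scale_bias * (c - origin) for c in curves]
        frame_pts = origin + model.scale_bias * (frame_pts - origin)

    if model.foreshortening_sd > 0:
        # all three records are 2-D projections of a domed palate; the
        # projection axis varies per acquisition, compressing the
        # anteroposterior (y) extent by a random factor
        sy = 1.0 + float(rng.normal(0.0, model.foreshortening_sd))
        sy = float(np.clip(sy, 0.6, 1.4))
        for arr in (*curves, frame_pts):
            arr[:, 1] = origin[1] + sy * (arr[:, 1] - origin[1])

    if model.projective_jitter > 0:
        j = model.projective_jitter
        a, b, c_, d = rng.normal(0.0, j, size=4)
        e, f = rng.normal(0.0, j / spec.arch_width, size=2)
        H = np.array([[1.0 + a, b, 0.0], [c_, 1.0 + d, 0.0], [e, f, 1.0]])
        curves = [origin + _project(c - origin, H) for c in curves]
        frame_pts = origin + _project(frame_pts - origin, H)

    if model.landmark_noise_sd > 0:
        # realized as a smooth vertical field along each ruga (coherent
        # curve distortion) plus independent frame-point noise, which shifts
        # the reference lines transversely and so moves landmarks along the
        # ruga — the dominant error of manual line placement
        sd_field = _FIELD_NOISE_FACTOR * model.landmark_noise_sd
        sd_frame = _FRAME_NOISE_FACTOR * model.landmark_noise_sd
        curves = [c + np.column_stack([np.zeros(len(c)),
                                       _smooth_noise_field(rng, c[:, 0], sd_field, half)])
                  for c in curves]
        frame_pts = frame_pts + rng.normal(0.0, sd_frame, size=frame_pts.shape)

    new_frame = IncisorFrame(
        collar_11=Point2D(*frame_pts[0]), collar_12=Point2D(*frame_pts[1]),
        collar_21=Point2D(*frame_pts[2]), collar_22=Point2D(*frame_pts[3]),
        interincisal=Point2D(*frame_pts[4]), sagittal_dir=palate.frame.sagittal_dir,
    )
    new_rugae = tuple(
        RugaCurve(tuple(Point2D(float(x), float(y)) for x, y in c), index=r.index)
        for c, r in zip(curves, palate.rugae))
    return new_frame, new_rugae


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: ground-truth palate plus per-modality landmark sets."""

    subject_id: str
    palate: SyntheticPalate
    landmark_sets: dict[str, LandmarkSet]


@dataclass(frozen=True)
class Cohort:
    """A synthetic study cohort with full ground-truth ledger."""

    subjects: tuple[SubjectRecord, ...]
    modality_models: dict[str, ModalityModel]
    master_seed: int

    def landmark_sets(self) -> list[LandmarkSet]:
        return [ls for s in self.subjects for ls in s.landmark_sets.values()]

    def __len__(self) -> int:
        return len(self.subjects)


def _draw_spec(rng: np.random.Generator, base: PalateSpec, seed: int) -> PalateSpec:
    """Per-subject anatomical variation around the base spec."""
    return replace(
        base,
        seed=seed,
        arch_width=float(np.clip(rng.normal(base.arch_width, _WIDTH_SD), 26.0, 38.0)),
        ruga_spacing=float(np.clip(rng.normal(base.ruga_spacing, _SPACING_SD), 3.0, 7.0)),
        ruga_wave_amplitude=float(np.clip(
            rng.normal(base.ruga_wave_amplitude, _AMP_SD), 0.5, 2.2)),
        ruga_wave_frequency=float(np.clip(
            rng.normal(base.ruga_wave_frequency, _FREQ_SD), 0.08, 0.22)),
        asymmetry=float(rng.uniform(0.5, 1.0)),
    )


def generate_cohort(n_subjects: int = 19,
                    modality_models: dict[str, ModalityModel] | None = None,
                    master_seed: int = 0,
                    base_spec: PalateSpec | None = None) -> Cohort:
    """Generate a cohort of per-subject modality triplets.

    Subject streams are spawned from a single seed sequence, so cohorts are
    reproducible and individual subjects independent of cohort ordering.
    """
    if n_subjects < 2:
        raise InvalidInputError("a cohort needs >= 2 subjects")
    models = dict(modality_models) if modality_models else default_modality_models()
    base = base_spec if base_spec is not None else PalateSpec()
    root = np.random.SeedSequence(master_seed)
    subject_seqs = root.spawn(n_subjects)
    subjects = []
    for s, seq in enumerate(subject_seqs):
        sid = f"S{s:03d}"
        spec_seq, *modality_seqs = seq.spawn(1 + len(models))
        rng = np.random.default_rng(spec_seq)
        spec = _draw_spec(rng, base, seed=int(rng.integers(0, 2**31 - 1)))
        try:
            palate = generate_palate(spec, subject_id=sid)
        except GenerationError as exc:
            raise GenerationError(f"subject {sid}: {exc}") from exc
        sets: dict[str, LandmarkSet] = {}
        for (name, model), mseq in zip(sorted(models.items()), modality_seqs):
            frame, rugae = apply_modality(palate, model, seed=mseq)
            sets[name] = extract_landmarks(frame, rugae[0], rugae[1],
                                           modality=model.kind, subject_id=sid)
        subjects.append(SubjectRecord(sid, palate, sets))
    return Cohort(tuple(subjects), models, master_seed)
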