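"""Reading and writing landmark and descriptor files.

Two landmark interchange formats are supported:

* **delimited text** — one row per landmark with columns
  ``subject_id, modality, landmark_index, x, y`` (landmark_index 1–6),
  any pandas-readable delimiter (default tab);
* **TPS** — the standard morphometrics format: ``LM=6`` blocks of
  whitespace-separated ``x y`` rows followed by ``IMAGE=`` (used here for
  the modality) and ``ID=`` (the subject label) lines.  Coordinates are
  written as given; no unit conversion is performed.

Descriptor tables are flat delimited files with family-prefixed columns
(``abs_d_1_2`` … ``mom_7``), one row per (subject, modality).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .exceptions import InvalidInputError
from .descriptors import DescriptorSet
from .landmarks import LandmarkSet

__all__ = [
    "landmark_sets_to_frame",
    "frame_to_landmark_sets",
    "read_landmarks",
    "write_landmarks",
    "read_tps",
    "write_tps",
    "write_descriptors",
    "write_cohort_config",
]

_COLUMNS = ["subject_id", "modality", "landmark_index", "x", "y"]


def landmark_sets_to_frame(sets: list[LandmarkSet]) -> pd.DataFrame:
    rows = [
        {"subject_id": ls.subject_id, "modality": ls.modality,
         "landmark_index": i, "x": p.x, "y": p.y}
        for ls in sets for i, p in enumerate(ls.pts, start=1)
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_landmark_sets(df: pd.DataFrame) -> list[LandmarkSet]:
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"landmark table is missing columns {sorted(missing)}")
    out: list[LandmarkSet] = []
    for (sid, mod), grp in df.groupby(["subject_id", "modality"], sort=True):
        grp = grp.sort_values("landmark_index")
        if list(grp["landmark_index"]) != [1, 2, 3, 4, 5, 6]:
            raise InvalidInputError(
                f"subject {sid!r} modality {mod!r}: expected landmark indices 1..6, "
                f"got {list(grp['landmark_index'])}")
        out.append(LandmarkSet.from_array(grp[["x", "y"]].to_numpy(float),
                                          modality=str(mod), subject_id=str(sid)))
    return out


def write_landmarks(sets: list[LandmarkSet], path: str | Path, sep: str = "\t") -> None:
    landmark_sets_to_frame(sets).to_csv(path, sep=sep, index=False)


def read_landmarks(path: str | Path, sep: str = "\t") -> list[LandmarkSet]:
    return frame_to_landmark_sets(pd.read_csv(path, sep=sep))


def write_tps(sets: list[LandmarkSet], path: str | Path) -> None:
    lines: list[str] = []
    for ls in sets:
        lines.append(f"LM={len(ls.pts)}")
        lines.extend(f"{p.x:.10g} {p.y:.10g}" for p in ls.pts)
        lines.append(f"IMAGE={ls.modality}")
        lines.append(f"ID={ls.subject_id}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tps(path: str | Path) -> list[LandmarkSet]:
    out: list[LandmarkSet] = []
    coords: list[tuple[float, float]] = []
    n_expected = modality = subject = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            if n_expected is not None:
                raise InvalidInputError("TPS block without terminating ID= line")
            n_expected = int(line.split("=", 1)[1])
            coords, modality, subject = [], None, None
        elif upper.startswith("IMAGE="):
            modality = line.split("=", 1)[1].strip()
        elif upper.startswith("SCALE="):
            continue  # scale factors are accepted but not applied
        elif upper.startswith("ID="):
            subject = line.split("=", 1)[1].strip()
            if n_expected is None or len(coords) != n_expected:
                raise InvalidInputError(
                    f"TPS block {subject!r}: expected {n_expected} coordinate rows, "
                    f"got {len(coords)}")
            out.append(LandmarkSet.from_array(
                coords, modality=modality or "photo", subject_id=subject))
            n_expected = None
        else:
            parts = line.split()
            if len(parts) != 2:
                raise InvalidInputError(f"unparseable TPS line: {raw!r}")
            coords.append((float(parts[0]), float(parts[1])))
    if n_expected is not None:
        raise InvalidInputError("TPS file ends inside a landmark block")
    return out


def write_descriptors(sets: list[DescriptorSet], path: str | Path,
                      sep: str = "\t") -> None:
    pd.DataFrame([d.to_row() for d in sets]).to_csv(path, sep=sep, index=False)


def write_cohort_config(cohort, path: str | Path) -> None:
    """Persist the generating configuration of a synthetic cohort (JSON)."""
    cfg = {
        "master_seed": cohort.master_seed,
        "n_subjects": len(cohort),
        "modality_models": {k: asdict(m) for k, m in cohort.modality_models.items()},
        "palate_specs": {s.subject_id: asdict(s.palate.spec) for s in cohort.subjects},
    }
    Path(path).write_text(json.dumps(cfg, indent=2) + "\n")
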