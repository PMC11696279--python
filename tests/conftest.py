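import numpy as np
import pytest

from rugometry.landmarks import LandmarkSet, extract_landmarks
from rugometry.simulate import PalateSpec, generate_cohort, generate_palate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def palate():
    """One deterministic synthetic palate with ground-truth landmarks."""
    return generate_palate(PalateSpec(seed=3), subject_id="P0")


@pytest.fixture(scope="session")
def landmark_set(palate) -> LandmarkSet:
    """Extracted landmarks of the session palate (chiral, well-conditioned)."""
    return extract_landmarks(palate.frame, palate.rugae[0], palate.rugae[1],
                             modality="photo", subject_id="P0")


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject cohort shared by the pipeline-level tests."""
    return generate_cohort(n_subjects=12, master_seed=0)


def random_simple_polygon(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random simple polygon: jittered radii at sorted angles."""
    ang = np.sort(rng.uniform(0, 2 * np.pi, n))
    rad = rng.uniform(1.0, 5.0, n)
    return np.column_stack([rad * np.cos(ang), rad * np.sin(ang)]) + rng.normal(0, 3, 2)


def shoelace(xy: np.ndarray) -> float:
    """Independent shoelace-formula area oracle."""
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))
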