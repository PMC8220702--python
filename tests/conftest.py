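import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from lesionmeter.ctio import CTSlice
from lesionmeter.phantom import PhantomSpec, ShapeFamily, sample_dataset, synthesize_lesion


@pytest.fixture(scope="session")
def circle_case():
    """3.2 cm circular lesion at 0.1 cm/px: apparent size exactly 32 px."""
    spec = PhantomSpec(
        shape_family=ShapeFamily.SMOOTH_ELLIPSE,
        true_diameter_cm=3.2,
        aspect_ratio=1.0,
        pixel_spacing_cm=0.1,
        rng_seed=7,
    )
    return synthesize_lesion(spec)


@pytest.fixture(scope="session")
def small_cohort():
    return sample_dataset(12, diameter_range_cm=(1.5, 4.5), spacing_range_cm=(0.07, 0.12), master_seed=42)


def slice_of(case) -> CTSlice:
    return CTSlice(pixels=case.image.astype(float), spacing_cm=(case.spacing_cm, case.spacing_cm))


def naive_longest_chord(mask: np.ndarray) -> float:
    """Independent O(n^2) oracle: max distance over all mask pixel pairs."""
    pts = np.argwhere(mask).astype(float)
    best = 0.0
    for i in range(len(pts)):
        d2 = ((pts[i + 1 :] - pts[i]) ** 2).sum(1)
        if len(d2):
            best = max(best, float(d2.max()))
    return float(np.sqrt(best))
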