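import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gestage import PhantomConfig, generate_cohort, normalize_sample, \
    select_slices

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")

PLANES = ("axial", "coronal", "sagittal")


def plane_arrays(subjects, plane="axial", n_slices=3):
    """Subjects -> ((n, n_slices, H, W) float32, age_days vector)."""
    xs, ys = [], []
    for s in subjects:
        slab = normalize_sample(
            select_slices(s.planes[plane], n_slices, plane=plane,
                          subject_id=s.subject_id))
        xs.append(slab.pixels)
        ys.append(s.age_days)
    return np.stack(xs).astype(np.float32), np.asarray(ys)


def multiplane_arrays(subjects, n_slices=3):
    x = {}
    for plane in PLANES:
        x[plane], y = plane_arrays(subjects, plane, n_slices)
    return x, y


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def small_cohort(phantom_config):
    return generate_cohort(phantom_config, 30, seed=7)
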