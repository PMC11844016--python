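import numpy as np
import pytest

import petsurv as ps


@pytest.fixture(scope="session")
def sphere_phantom():
    """Noiseless uniform sphere: radius 10 mm on a 2 mm isotropic grid."""
    cfg = ps.PhantomConfig(
        grid_shape=(48, 48, 48),
        voxel_size_mm=(2.0, 2.0, 2.0),
        background_suv=1.0,
        lesions=[
            ps.LesionSpec(center_mm=(48, 48, 48), radii_mm=(10, 10, 10),
                          peak_suv=10.0)
        ],
    )
    return ps.generate_phantom(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """One paper-scale cohort under the default study conditions."""
    return ps.generate_cohort(ps.CohortConfig(rng_seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient cohort with a strong step hazard (fast fits)."""
    cfg = ps.CohortConfig(
        n_patients=60, beta_tlg=np.log(4.0), rng_seed=11, dropout_rate=0.1
    )
    return ps.generate_cohort(cfg)


def make_survival_arrays(rng, n, beta=0.7, censor_scale=8.0):
    """Simple continuous-time survival data for array-level Cox tests."""
    x = rng.normal(size=n)
    t = rng.exponential(1.0 / (0.1 * np.exp(beta * x)))
    c = rng.uniform(0, censor_scale, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return x, time, event
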