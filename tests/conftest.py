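import numpy as np
import pytest

from ensemblefit import NamfisFitter, SyntheticScenario, realize, restraints_from_realization
from ensemblefit.synthetic_data import build_conformer, generate_pool


@pytest.fixture(scope="session")
def template():
    return build_conformer()


@pytest.fixture(scope="session")
def small_pool():
    return generate_pool(11, 8)


@pytest.fixture(scope="session")
def zero_noise_study():
    """One fully realized noiseless scenario with calibrated restraints."""
    scenario = SyntheticScenario(seed=42)
    real = realize(scenario)
    drs, jrs = restraints_from_realization(real)
    return real, drs, jrs


@pytest.fixture(scope="session")
def fitted_zero_noise(zero_noise_study):
    real, drs, jrs = zero_noise_study
    fitter = NamfisFitter(random_state=7).fit(real.pool, drs, jrs)
    return real, drs, jrs, fitter


def random_rotation(rng):
    """Uniform-ish random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
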