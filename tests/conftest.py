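import numpy as np
import pytest

import desgp


@pytest.fixture(scope="session")
def spec():
    return desgp.SyntheticSpec(n_compounds=20, seed=11)


@pytest.fixture(scope="session")
def profiles(spec):
    return desgp.gen_profiles(spec)


@pytest.fixture(scope="session")
def density_ds(spec, profiles):
    return desgp.gen_dataset(spec, "density", 150, profiles)


@pytest.fixture(scope="session")
def viscosity_ds(spec, profiles):
    return desgp.gen_dataset(spec, "viscosity", 150, profiles)


@pytest.fixture(scope="session")
def melting_ds(spec, profiles):
    return desgp.gen_dataset(spec, "melting_temperature", 150, profiles)


@pytest.fixture(scope="session")
def gauss_profile():
    """A single synthetic Gaussian-bump profile on the canonical grid."""
    centers = desgp.CANONICAL_GRID.centers()
    vals = 40.0 * np.exp(-(centers**2) / (2 * 0.005**2))
    return desgp.SigmaProfile(compound_id="bump", values=vals)


@pytest.fixture(scope="session")
def small_gp_problem():
    """A small random regression problem with GP-generated labels."""
    rng = np.random.default_rng(5)
    X = rng.uniform(0, 2, size=(30, 4))
    y = np.sin(X[:, 0] * 3) + 0.5 * X[:, 1] + rng.normal(0, 0.05, 30) + 2.0
    return X, y
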