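import numpy as np
import pytest

from gpcochlea.synthetic import (
    PopulationParams,
    SpiralParams,
    make_synthetic_cochlea,
    sample_population,
)


@pytest.fixture(scope="session")
def default_cochlea():
    """One synthetic scala tympani with default spiral parameters + truth."""
    return make_synthetic_cochlea()


@pytest.fixture(scope="session")
def footprint_cochlea():
    """Synthetic cochlea generated toward the mean footprint A=3.8, B=2.8."""
    return make_synthetic_cochlea(SpiralParams(target_footprint=(3.8, 2.8)))


@pytest.fixture(scope="session")
def cohort12():
    """Small heterogeneous cohort for LOOCV behaviour tests."""
    return sample_population(PopulationParams(n=12, seed=42))


@pytest.fixture(scope="session")
def cohort38():
    """Cohort of the published sample size, default population statistics."""
    return sample_population(PopulationParams(n=38, seed=1))


def rigid_transform(rng: np.random.Generator):
    """A random rotation matrix and translation vector."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.normal(scale=5.0, size=3)
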