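import numpy as np
import pytest

from jmsim.synthetic_data import (
    RandomEffectsSpec,
    ScenarioConfig,
    SurvivalSpec,
    TrajectorySpec,
    generate_dataset,
)


@pytest.fixture(scope="session")
def base_cfg():
    """Base scenario with all generating parameters at their defaults."""
    return ScenarioConfig(seed=2024)


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced-size scenario for fast estimator tests."""
    return ScenarioConfig(n_subjects=60, seed=515)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg, 0)


@pytest.fixture(scope="session")
def base_dataset(base_cfg):
    return generate_dataset(base_cfg, 0)


@pytest.fixture
def noisefree_cfg():
    """Degenerate scenario: no random effects, no measurement error."""
    return ScenarioConfig(
        n_subjects=80,
        ranef=RandomEffectsSpec(D=((0.0, 0.0), (0.0, 0.0))),
        sigma_eps=0.0,
        seed=99,
    )


@pytest.fixture
def null_survival():
    """Survival spec with no covariate or biomarker effects, unit scale."""
    return SurvivalSpec(phi=1.97, gamma_age=0.0, gamma_sex=0.0, alpha=0.0,
                        gamma0=0.0)


@pytest.fixture
def linear_traj():
    return TrajectorySpec()


def rng(seed=0):
    return np.random.default_rng(seed)
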