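import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import poolmove as pm

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def design6() -> pm.StudyDesign:
    """The six-pool, 42-occasion study design."""
    return pm.illinois_design()


@pytest.fixture(scope="session")
def design2() -> pm.StudyDesign:
    """A two-pool, 24-occasion design for reduced-scale fits."""
    return pm.StudyDesign(pools=("A", "B"), start=(2012, 3), n_occasions=24)


@pytest.fixture(scope="session")
def theta2() -> pm.ParameterSet:
    """Well-identified two-pool truth used by the recovery simulations."""
    return pm.ParameterSet(
        phi=0.95,
        psi=np.array([[0.8, 0.2], [0.1, 0.9]]),
        rho=np.full((2, 4), 0.7),
    )


@pytest.fixture(scope="session")
def recovery_data2(design2, theta2):
    """One cohort-release dataset (N=200, T=24) from the two-pool truth."""
    cfg = pm.SimulationConfig(
        design=design2,
        theta_true=theta2,
        release_counts=(100, 100),
        release_window=(1, 1),
        seed=1,
    )
    histories, states = pm.simulate_histories(cfg)
    return cfg, histories, states


def random_theta(m: int, rng: np.random.Generator) -> pm.ParameterSet:
    """A random valid parameter set (Dirichlet rows, uniform detections)."""
    psi = rng.dirichlet(np.ones(m), size=m)
    rho = rng.uniform(0.05, 0.95, size=(m, 4))
    return pm.ParameterSet(phi=float(rng.uniform(0.5, 1.0)), psi=psi, rho=rho)
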