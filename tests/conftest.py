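import numpy as np
import pytest

from cohortmslt.panel import DISABLED, NONDISABLED
from cohortmslt.ppo import PPOModel, TransitionMatrixSet
from cohortmslt.synthetic import default_study_configs, generate_panel


@pytest.fixture(scope="session")
def small_octo_panel():
    """A modest octogenarian earlier-cohort panel (deaths, dropout, 2-year waves)."""
    config = default_study_configs()["octogenarian_earlier"]
    config.n_individuals = 1500
    return generate_panel(config, seed=42)


@pytest.fixture(scope="session")
def truth_models():
    """Well-conditioned truth models used for estimator checks (balanced
    outcome categories, so coefficient information is high)."""
    nd = PPOModel(origin=NONDISABLED, center=80.0, alpha=(0.0, 1.1),
                  shared={"age": -0.08},
                  gamma={"woman": (-0.2, 0.25), "rural": (-0.1, -0.15),
                         "schooled": (0.15, 0.1)})
    d = PPOModel(origin=DISABLED, center=80.0, alpha=(-0.6, 0.7),
                 shared={"age": -0.07},
                 gamma={"woman": (-0.15, 0.2), "rural": (-0.1, -0.1),
                        "schooled": (0.1, 0.1)})
    return nd, d


def constant_mortality_matrices(q: float = 0.1, ages=(80, 89)) -> TransitionMatrixSet:
    """Matrices with constant annual death probability q from both living
    states and no disability transitions."""
    rng = np.arange(ages[0], ages[1] + 1)
    probs = np.zeros((len(rng), 8, 3, 3))
    probs[:, :, 0, 0] = 1 - q
    probs[:, :, 0, 2] = q
    probs[:, :, 1, 1] = 1 - q
    probs[:, :, 1, 2] = q
    probs[:, :, 2, 2] = 1.0
    return TransitionMatrixSet(ages=rng, probs=probs)


def random_matrix_set(rng: np.random.Generator, ages=(80, 89)) -> TransitionMatrixSet:
    """A random valid transition-matrix set (rows Dirichlet, dead absorbing)."""
    span = np.arange(ages[0], ages[1] + 1)
    probs = np.zeros((len(span), 8, 3, 3))
    probs[:, :, 0, :] = rng.dirichlet([8.0, 1.5, 1.0], size=(len(span), 8))
    probs[:, :, 1, :] = rng.dirichlet([1.5, 5.0, 2.0], size=(len(span), 8))
    probs[:, :, 2, 2] = 1.0
    return TransitionMatrixSet(ages=span, probs=probs)
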