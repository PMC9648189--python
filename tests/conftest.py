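"""Shared fixtures: model wavefunctions, solvents, samplers, evaluators.

Expensive objects (10^5-snapshot Metropolis runs, S^2 profile evaluators)
are session-scoped so module tests and the acceptance tests reuse them.
"""

import numpy as np
import pytest

import solvdisp as sd


@pytest.fixture(scope="session")
def gauss_wf():
    return sd.gaussian_wavefunction(1.0)


@pytest.fixture(scope="session")
def hydrogen_wf():
    return sd.hydrogen_like_wavefunction(1.0)


@pytest.fixture(scope="session")
def damping():
    return sd.DampingSpec(1.6)


@pytest.fixture(scope="session")
def cyclohexane():
    return sd.SolventModel.from_table("cyclohexane")


@pytest.fixture(scope="session")
def water():
    return sd.SolventModel.from_table("water")


@pytest.fixture(scope="session")
def two_state_pair():
    """Diffuseness-ratio-2 pair (large contrast for sign/moment checks)."""
    return sd.make_two_state_fixture(2.0, sigma0=1.0)


@pytest.fixture(scope="session")
def synthetic_system():
    """The packaged study conditions: ratio 1.25, sigma0 1.2, cyclohexane."""
    return sd.synthetic_two_state_system()


@pytest.fixture(scope="session")
def hydrogen_sample(hydrogen_wf):
    return sd.sample_configurations(hydrogen_wf, 100_000, seed=11)


@pytest.fixture(scope="session")
def gauss_sample(gauss_wf):
    return sd.sample_configurations(gauss_wf, 100_000, seed=12)


def blocked_se(values: np.ndarray, n_blocks: int = 25) -> float:
    """Standard error of the mean from block averages (handles autocorrelation)."""
    blocks = np.array_split(values, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / np.sqrt(len(means)))
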