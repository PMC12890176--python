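import numpy as np
import pytest

from rciburn import ParameterSet, baseline_parameters
from rciburn.model import STATE_NAMES


@pytest.fixture(scope="session")
def baseline() -> ParameterSet:
    """Midpoint-of-initial-range parameter set (the shipped baseline)."""
    return baseline_parameters()


@pytest.fixture(scope="session")
def representative() -> ParameterSet:
    """Representative set shipped with the package."""
    from importlib import resources

    path = resources.files("rciburn.data") / "representative_params.yaml"
    return ParameterSet.from_yaml(str(path))


def random_states(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random plausible non-negative states (cells O(1), damage O(1))."""
    return rng.uniform(0.0, 1.5, size=(n, len(STATE_NAMES)))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
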