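import numpy as np
import pytest

from levyrisk.environment import Environment, EnvironmentConfig, generate_environment
from levyrisk.geometry import Torus


@pytest.fixture
def rng():
    return np.random.default_rng(20251109)


@pytest.fixture
def torus():
    return Torus(500.0)


@pytest.fixture
def env_cfg():
    """The standard sparse patchy landscape."""
    return EnvironmentConfig()


@pytest.fixture
def env(env_cfg):
    return generate_environment(env_cfg, np.random.default_rng(42))


def make_bare_environment(target_pos=(250.0, 250.0), L=500.0):
    """Minimal valid environment: one patch, one target, placed explicitly.

    Useful for episode tests that need full control over what the searcher
    can encounter.
    """
    cfg = EnvironmentConfig(L=L, n_targets=1, n_patches=1)
    patch_xy = np.array([[target_pos[0], target_pos[1]]])
    target_xy = np.array([[target_pos[0], target_pos[1]]])
    return Environment(cfg, patch_xy, target_xy, np.array([0]))
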