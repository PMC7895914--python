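import numpy as np
import pytest

from coarsegame import (GameConfig, Strategy, UtilityParams, make_beta,
                        make_truncated_uniform)


@pytest.fixture
def uniform():
    return make_truncated_uniform(0.0, 1.0)


@pytest.fixture
def beta_half():
    """U-shaped arcsine distribution: strongly informative signals."""
    return make_beta(0.5, 0.5)


@pytest.fixture
def beta_peaked():
    """Signals concentrated near 1/2: nearly uninformative."""
    return make_beta(20.0, 20.0)


@pytest.fixture
def beta_skewed():
    """Right-skewed: mostly non-bacterial presentations."""
    return make_beta(1.0, 5.0)


def params(alpha=0.1, c=0.0, r1=0.0, r2=1.0, r3=2.0):
    return UtilityParams(r1=r1, r2=r2, r3=r3, c=c, alpha=alpha)


@pytest.fixture
def make_cfg():
    """Factory: game config with U = alpha (r2 - r1 = 1) and e0 = M*alpha = 1."""
    def _make(dist, M):
        return GameConfig(M=M, dist=dist, params=params(alpha=1.0 / M))
    return _make


@pytest.fixture
def unit_params():
    return params(alpha=1.0)


def constant_strategy(d, M):
    return Strategy(np.full(M, float(d)))
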