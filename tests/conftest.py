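import numpy as np
import pytest

from supercoilsim import FiberSystem, ForceFieldParams, IntegratorSettings


@pytest.fixture(scope="session")
def params():
    return ForceFieldParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def perturbed_chain(n=10, seed=0, closed=False):
    """Small mildly-perturbed chain with a valid frame, for force tests."""
    r = np.random.default_rng(seed)
    if closed:
        radius = 0.5 / np.sin(np.pi / n)
        ang = 2 * np.pi * np.arange(n) / n
        pos = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)])
    else:
        pos = np.zeros((n, 3))
        pos[:, 0] = np.arange(n, dtype=float)
    pos = pos + 0.08 * r.standard_normal((n, 3))
    side = pos + np.array([0.0, 0.0, 0.5]) + 0.04 * r.standard_normal((n, 3))
    return pos, side


@pytest.fixture()
def small_system():
    pos, side = perturbed_chain(10, seed=3)
    return FiberSystem(positions=pos, side_sites=side, closed=False, box=200.0)


@pytest.fixture(scope="session")
def fast_settings():
    return IntegratorSettings(dt=1e-3, n_steps=1000, report_every=100, seed=7)
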