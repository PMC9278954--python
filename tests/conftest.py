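import numpy as np
import pytest

from crhnet import (CRH_PARAMS_MEAN, AdExParams, NetworkConfig,
                    RbSsGeneratorParams, StepProtocol, SpikeTrain,
                    generate_rb_ss_train)


@pytest.fixture(scope="session")
def mean_params() -> AdExParams:
    return CRH_PARAMS_MEAN


@pytest.fixture(scope="session")
def linear_params() -> AdExParams:
    """A parameter set whose exponential term is negligible at rest, so
    subthreshold behavior is analytically linear."""
    return AdExParams(C=22.0, g_L=0.9, E_L=-67.9, Delta_T=2.0, V_T=-45.0,
                      V_R=-58.8, tau_w=98.2, a=0.0, b=17.9)


@pytest.fixture(scope="session")
def short_protocol() -> StepProtocol:
    """A compact 6-sweep step protocol for fast fitting tests."""
    return StepProtocol.patch_default(n_sweeps=6, dt=0.1)


@pytest.fixture(scope="session")
def rb_train_600s():
    """Default-calibration RB/SS train, 600 s, with ground-truth labels."""
    return generate_rb_ss_train(RbSsGeneratorParams(seed=42), duration=600.0)


@pytest.fixture(scope="session")
def small_network_config() -> NetworkConfig:
    """In-degree-preserving scaled network for fast integration tests."""
    import dataclasses
    return dataclasses.replace(NetworkConfig().scaled(100, 100), seed=7)


def random_train(rng, n_max=120, burstiness=0.5, duration=60.0) -> SpikeTrain:
    """Random spike train mixing burst-range and long ISIs."""
    n = rng.integers(2, n_max)
    isis = np.where(rng.random(n) < burstiness,
                    rng.uniform(0.001, 0.03, n),
                    rng.exponential(0.3, n) + 0.003)
    t = np.cumsum(isis)
    t = t[t < duration]
    if t.size < 2:
        t = np.array([0.1, 0.2])
    return SpikeTrain(times=t, t_start=0.0, t_stop=duration)
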