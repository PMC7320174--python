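import numpy as np
import pytest
from hypothesis import settings

import zring

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_config():
    return zring.RingSimConfig()


@pytest.fixture(scope="session")
def noise_free_movie():
    """Expectation movie of a rotating ring (no Poisson noise)."""
    cfg = zring.RingSimConfig(noise=False, bleach_rate=0.0)
    return cfg, zring.simulate_ring_movie(cfg)


@pytest.fixture(scope="session")
def noisy_movie():
    cfg = zring.RingSimConfig(seed=7)
    return cfg, zring.simulate_ring_movie(cfg)


@pytest.fixture(scope="session")
def static_noise_free_movie():
    cfg = zring.RingSimConfig(speed=0.0, bleach_rate=0.0, noise=False)
    return cfg, zring.simulate_ring_movie(cfg)


def roi_for(cfg: zring.RingSimConfig) -> zring.RingROI:
    return zring.RingROI(center=cfg.center, radius_px=cfg.radius / cfg.pixel_size)


def true_slope(cfg: zring.RingSimConfig, kym: zring.Kymograph) -> float:
    """Ground-truth stripe slope in columns/row."""
    return cfg.speed * kym.frame_interval / kym.arc_step


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
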