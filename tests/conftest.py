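import numpy as np
import pytest

import assocmem as am


@pytest.fixture(scope="session")
def ring100():
    return am.build_ring_chain(100)


@pytest.fixture(scope="session")
def karate():
    return am.build_karate()


@pytest.fixture(scope="session")
def tiny_ring():
    """Small ring for fast dynamics tests."""
    return am.build_ring_chain(10)


@pytest.fixture(scope="session")
def tiny_config():
    """Scaled-down population sizes that keep a trial under a second."""
    return am.SimulationConfig(n_e=400, n_g=50, n_l=50, f=0.05, n_li=5,
                               t_end=120.0, t_stim=40.0)


@pytest.fixture(scope="session")
def tiny_network(tiny_ring, tiny_config):
    cfg = tiny_config
    return am.build_network(tiny_ring, n_e=cfg.n_e, n_g=cfg.n_g, n_l=cfg.n_l,
                            f=cfg.f, n_li=cfg.n_li, p_eg=cfg.p_eg,
                            p_ge=cfg.p_ge, seed=42)


def random_correlation_like(rng, p):
    """A symmetric matrix with unit diagonal and entries in [-1, 1]."""
    a = rng.uniform(-1.0, 1.0, size=(p, p))
    c = (a + a.T) / 2.0
    np.fill_diagonal(c, 1.0)
    return c
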