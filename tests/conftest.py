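import numpy as np
import pytest

import beaconshield as bs


def random_beacon_instance(rng, n_max=5, m_max=8):
    """Small random Beacon panel with Hardy–Weinberg carriers."""
    n = int(rng.integers(2, n_max + 1))
    m = int(rng.integers(3, m_max + 1))
    p = rng.uniform(0.01, 0.45, m)
    q = 1.0 - (1.0 - p) ** 2
    d = (rng.random((n, m)) < q).astype(int)
    d_ref = (rng.random((n, m)) < q).astype(int)
    return bs.build_panel(d, d_ref, p, gamma=1e-6, mode=bs.BEACON)


@pytest.fixture
def tiny_beacon():
    """Deterministic 3-member, 4-SNV Beacon panel."""
    d = np.array([[1, 0, 1, 0],
                  [0, 1, 1, 0],
                  [0, 0, 1, 0]])
    d_ref = np.array([[0, 1, 0, 0],
                      [1, 0, 0, 0],
                      [0, 0, 1, 0]])
    p = np.array([0.1, 0.2, 0.3, 0.05])
    panel = bs.build_panel(d, d_ref, p, gamma=1e-6, mode=bs.BEACON)
    return panel, bs.compute_constants(panel), bs.make_release(panel)


@pytest.fixture
def tiny_aaf():
    """Deterministic 4-member, 3-SNV AAF panel."""
    d = np.array([[1, 0, 1],
                  [0, 0, 1],
                  [1, 1, 0],
                  [0, 0, 0]])
    d_ref = np.array([[0, 1, 0],
                      [1, 0, 1],
                      [0, 0, 0],
                      [1, 1, 0]])
    p = np.array([0.1, 0.2, 0.3])
    panel = bs.build_panel(d, d_ref, p, gamma=1e-6, mode=bs.AAF)
    return panel, bs.make_release(panel)


@pytest.fixture
def sim_beacon_panel():
    cfg = bs.SimulationConfig(n=30, n_ref=30, m=120, seed=7)
    panel = bs.simulate_panel(cfg)
    return panel, bs.compute_constants(panel), bs.make_release(panel)
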