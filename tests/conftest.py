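import numpy as np
import pytest

from nicheweb import BipartiteNetwork, BPNMParams


@pytest.fixture
def small_net():
    """3x3 network with distinct column degrees (1, 3, 2)."""
    a = np.array([[1, 1, 1],
                  [0, 1, 1],
                  [0, 1, 0]])
    return BipartiteNetwork(a, ("r1", "r2", "r3"), ("c1", "c2", "c3"))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_network(rng, s_r=6, s_c=6, p=0.4):
    """Random binary matrix guaranteed at least one link."""
    while True:
        a = (rng.random((s_r, s_c)) < p).astype(int)
        if a.sum() >= 1:
            return BipartiteNetwork(a)


def random_bpnm_params(rng, s_r=8, s_c=8):
    return BPNMParams(
        n=rng.uniform(0, 1, s_r),
        c=rng.uniform(0, 1, s_c),
        r=rng.uniform(0.05, 1.5, s_c),
        g=rng.uniform(1, 6),
        p_max=rng.uniform(0.3, 1.0),
    )
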