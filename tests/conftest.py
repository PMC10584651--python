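import numpy as np
import pytest

from bbvs.model_core import Block, GroupedDesign, Stage1Hyper


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_design(rng):
    """Small grouped design: n=12, three groups of width 3."""
    n = 12
    X0 = np.column_stack([np.ones(n), rng.standard_normal(n)])
    blocks = [
        Block(f"b{g}", np.arange(3 * g, 3 * (g + 1)),
              rng.standard_normal((n, 3)))
        for g in range(3)
    ]
    return GroupedDesign(X0=X0, blocks=blocks, ridge=1.0)


@pytest.fixture
def toy_hyper():
    return Stage1Hyper(h0=2.0, c0=1.5, nu0=4.0, sigma0_sq=0.8)
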