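import numpy as np
import pytest
from hypothesis import settings

from xylopat.chain import ResidueState, XylanChain

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

# Residue-type probabilities (X, X2, X3, X23) measured by HSQC integration
# for the GlcA-less mutant and wild-type Arabidopsis xylan.
GUX1GUX2_COMPOSITION = (0.556, 0.153, 0.266, 0.025)
WT_COMPOSITION = (0.468, 0.267, 0.222, 0.043)


def make_chain(dp, ac2=(), ac3=()):
    """Chain with acetyl flags at the given 1-based (reducing-end) positions."""
    return XylanChain(
        tuple(
            ResidueState(i, ac2=(i in set(ac2)), ac3=(i in set(ac3)))
            for i in range(1, dp + 1)
        )
    )


@pytest.fixture
def alternating_ac3():
    """Strictly alternating 3-O-acetylated chains (acetyl on even positions)."""

    def _make(dp):
        return make_chain(dp, ac3=range(2, dp + 1, 2))

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
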