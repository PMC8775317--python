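import numpy as np
import pytest

from complexscape.synthetic_scenes import build_scene


@pytest.fixture(scope="session")
def canonical_scene():
    """The default three-regime, four-band synthetic scene."""
    return build_scene(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
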