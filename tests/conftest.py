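from dataclasses import replace

import numpy as np
import pytest

from hiegrade.synth import SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_synth_cfg():
    """Desk-scale generator configuration: 30 s records."""
    return replace(SynthConfig(), duration=30.0)


@pytest.fixture
def minute_synth_cfg():
    return replace(SynthConfig(), duration=60.0)
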