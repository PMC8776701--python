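import numpy as np
import pytest

from ventdose import GriddedVolume


def volume(values, spacing=(1.0, 1.0, 1.0), kind="HU"):
    return GriddedVolume(np.asarray(values, dtype=float), spacing, kind=kind)


def full_mask(shape, spacing=(1.0, 1.0, 1.0)):
    return GriddedVolume(np.ones(shape), spacing, kind="mask")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
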