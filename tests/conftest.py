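import numpy as np
import pytest

from groupsim import GroupSample, ScaleSpec


@pytest.fixture
def likert6() -> ScaleSpec:
    return ScaleSpec(1, 6, 6)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_group(label, values, scale):
    return GroupSample(label, np.asarray(values, dtype=float), scale)


@pytest.fixture
def small_pair(likert6):
    a = make_group("A", [1, 2, 3], likert6)
    b = make_group("B", [2, 3, 4], likert6)
    return a, b
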