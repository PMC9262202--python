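import numpy as np
import pytest

from lpda.core import TwoGroupData
from lpda.simulate import GeneratorSpec, generate_two_groups


@pytest.fixture
def separable_1d() -> TwoGroupData:
    """X = {2, 3}, Y = {-2, -3}: strictly separable in one dimension."""
    return TwoGroupData([[2.0], [3.0]], [[-2.0], [-3.0]], labels=("A", "B"))


@pytest.fixture
def symmetric_1d() -> TwoGroupData:
    """X = {-1, 1}, Y = {-2, 2}: both weighted centroids are 0."""
    return TwoGroupData([[-1.0], [1.0]], [[-2.0], [2.0]], labels=("A", "B"))


@pytest.fixture
def separable_gaussians() -> TwoGroupData:
    """Two 2-D Gaussian clouds 10 noise-sd apart: separable with huge margin."""
    sim = generate_two_groups(GeneratorSpec("separable_lowdim", seed=1))
    return sim.data


@pytest.fixture
def overlapping_gaussians() -> TwoGroupData:
    sim = generate_two_groups(GeneratorSpec("overlapping_lowdim", seed=7))
    return sim.data


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220707)
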