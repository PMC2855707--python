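import numpy as np
import pytest

from rilcross import ALL_NAMES, GenerationMeans, expected_generation_means


def means_from_dict(means, variance=1.0, n=1):
    """GenerationMeans with identical variance/n for every generation."""
    return GenerationMeans({g: (m, variance, n) for g, m in means.items()})


@pytest.fixture
def equal_variance_means():
    """All seven generation means from known effects, unit Var(mean)."""
    effects = {"mu": 100.0, "A": 3.0, "D": 5.0, "AA": 2.0, "AD": -1.5,
               "DD": 4.0}
    means = expected_generation_means(effects, ALL_NAMES)
    return effects, means_from_dict(means, variance=1.0, n=1)


@pytest.fixture
def rng():
    return np.random.default_rng(20231114)
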