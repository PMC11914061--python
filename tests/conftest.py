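import numpy as np
import pytest

from slgcfate.synthetic import GeneratorTruth, generate_cohort


class ScriptedRng:
    """Stand-in generator returning scripted values for unit arithmetic tests."""

    def __init__(self, beta=0.3, uniform=1.0, normal=0.0, exponential=0.0, random=0.5):
        self._beta = beta
        self._uniform = uniform
        self._normal = normal
        self._exponential = exponential
        self._random = random

    def beta(self, a, b):
        return self._beta

    def uniform(self, lo=0.0, hi=1.0, size=None):
        return self._uniform

    def normal(self, loc=0.0, scale=1.0, size=None):
        return self._normal

    def exponential(self, scale=1.0, size=None):
        return self._exponential

    def random(self):
        return self._random


@pytest.fixture
def scripted_rng():
    return ScriptedRng


@pytest.fixture(scope="session")
def default_truth():
    return GeneratorTruth()


@pytest.fixture(scope="session")
def clean_truth():
    """Truth without the asymmetry noise factor: the division asymmetry is
    then an exact truncated beta, so input-distribution fits close the loop."""
    return GeneratorTruth(noise_mode="off")


@pytest.fixture(scope="session")
def clean_cohort(clean_truth):
    """Noise-free-asymmetry cohort, 4 individuals x 500 cells."""
    return generate_cohort(clean_truth, n_individuals=4, n_cells=500, seed=101)


@pytest.fixture(scope="session")
def small_cohort(default_truth):
    """Default-condition cohort at data scale (4 x 65 cells)."""
    return generate_cohort(default_truth, n_individuals=4, n_cells=65, seed=7)
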