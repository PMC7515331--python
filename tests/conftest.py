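import numpy as np
import pytest

from apchip import MotifProblem, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def planted_easy():
    """A small planted (10, 1) dataset where recovery is near-certain."""
    problem = MotifProblem(l=10, d=1, t=12, n=120, q=12)
    dataset, truth = simulate_dataset(problem, seed=42)
    return problem, dataset, truth
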