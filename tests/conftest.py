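import numpy as np
import pytest

from alphaiw import AIWParams, datasets

# the eight (alpha, beta) study settings, sigma = 1
STUDY_TRIPLES = [
    (0.8, 0.5, 1.0), (0.7, 0.9, 1.0), (1.5, 0.8, 1.0), (0.9, 1.7, 1.0),
    (2.0, 1.5, 1.0), (1.7, 2.5, 1.0), (1.0, 1.0, 1.0), (2.0, 2.0, 1.0),
]


@pytest.fixture(scope="session")
def kevlar49():
    return datasets.load("kevlar49").sample


@pytest.fixture(scope="session")
def kevlar373():
    return datasets.load("kevlar373").sample


@pytest.fixture(params=STUDY_TRIPLES, ids=lambda t: f"a{t[0]}-b{t[1]}")
def study_params(request):
    return AIWParams(*request.param)


@pytest.fixture
def log_grid():
    return np.logspace(-2, 2, 60)
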