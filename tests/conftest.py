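import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = np.count_nonzero(a | b)
    return np.count_nonzero(a & b) / union if union else 1.0
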