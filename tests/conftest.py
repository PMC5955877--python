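import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from erenorm.data_model import QuantityMatrix

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def random_quantity_matrix(rng: np.random.Generator, n_samples: int, n_targets: int) -> QuantityMatrix:
    """Random valid quantity matrix via a random Cq matrix (factor 2)."""
    cq = rng.uniform(18.0, 30.0, size=(n_samples, n_targets))
    q = 2.0 ** (cq.min(axis=0)[None, :] - cq)
    samples = [f"s{i}" for i in range(n_samples)]
    targets = [f"t{j:02d}" for j in range(n_targets)]
    return QuantityMatrix(samples, targets, q)


@pytest.fixture
def rng():
    return np.random.default_rng(20180516)
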