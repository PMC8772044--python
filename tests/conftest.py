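import logging

import numpy as np
import pytest

from mcsdti.containers import FeatureMatrix, InteractionMatrix, SimilarityMatrix
from mcsdti.synthetic import GeneratorConfig, generate_dataset

logging.getLogger("mcsdti").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-world synthetic dataset (54 drugs x 26 targets, 6.4% density)."""
    return generate_dataset(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """A faster, lower-dimensional dataset for per-operation tests."""
    cfg = GeneratorConfig(u=30, v=12, p=64, q=20, density=0.1, seed=3)
    return generate_dataset(cfg)


@pytest.fixture
def tiny_Y():
    # degrees per target: t0=3, t1=1, t2=0
    values = np.array(
        [
            [1, 0, 0],
            [1, 1, 0],
            [1, 0, 0],
            [0, 0, 0],
        ]
    )
    return InteractionMatrix(("d1", "d2", "d3", "d4"), ("t0", "t1", "t2"), values)


@pytest.fixture
def identity_sim():
    def make(ids):
        return SimilarityMatrix(tuple(ids), np.eye(len(ids)))

    return make
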