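import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))  # make `oracles` importable

from handmuscle import (
    BinaryMask,
    PhantomSpec,
    PipelineConfig,
    ScalarVolume,
    make_dixon_phantom,
    make_t1_phantom,
    prepare_dataset,
)


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec(seed=0)


@pytest.fixture(scope="session")
def phantom(default_spec):
    """Default T1 phantom: (t1, csa_truth, muscle_truth)."""
    return make_t1_phantom(default_spec)


@pytest.fixture(scope="session")
def dixon(default_spec, phantom):
    _, _, muscle = phantom
    return make_dixon_phantom(default_spec, muscle)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def prepared(phantom, config):
    """Preprocessed default phantom: (normalized, hand, peaks)."""
    t1, _, _ = phantom
    return prepare_dataset(t1, config)


@pytest.fixture(scope="session")
def small_cohort():
    """Five small phantoms for quick training tests: (t1, csa, muscle)."""
    specs = [PhantomSpec(shape=(8, 64, 64), seed=s) for s in range(5)]
    return [make_t1_phantom(s) for s in specs]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_mask(rng, shape=(6, 9, 8), spacing=(0.5, 0.5, 3.0), p=0.35) -> BinaryMask:
    data = rng.random(shape) < p
    if not data.any():
        data[tuple(s // 2 for s in shape)] = True
    return BinaryMask(data, spacing)


def tiny_volume(rng, shape=(3, 15, 15), spacing=(0.5, 0.5, 3.0)) -> ScalarVolume:
    return ScalarVolume(rng.normal(100.0, 25.0, shape).astype(np.float32), spacing)
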