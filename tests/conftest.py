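import numpy as np
import pytest

from gradmapseg import PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Five deterministic phantom patients at the default study conditions."""
    return generate_cohort(PhantomConfig(), 5, seed=7)


@pytest.fixture(scope="session")
def clean_cohort():
    """High-contrast cohort, no disappearance, sub-margin registration offsets."""
    cfg = PhantomConfig(disappear_prob=0.0, reg_offset_range=(0, 1))
    return generate_cohort(cfg, 10, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_blob(rng, shape=(12, 12, 12), p=0.2, ensure_nonempty=True):
    """Random sparse binary mask for oracle comparisons."""
    m = rng.random(shape) < p
    if ensure_nonempty and not m.any():
        m[tuple(rng.integers(0, s) for s in shape)] = True
    return m
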