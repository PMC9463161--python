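import numpy as np
import pytest

import gaitgan as gg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Six-subject paired-visit cohort, small enough for fast training tests."""
    return gg.SimConfig(n_subjects=6, visits_per_subject=2, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return gg.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_examples(small_cohort):
    return gg.preprocess_cohort(small_cohort)


def random_paired_batch(n_pairs: int, rng: np.random.Generator) -> gg.PairedBatch:
    """Arbitrary valid paired batch with random predictions and truths."""
    n = 2 * n_pairs
    pair = np.arange(n)
    pair[0::2] += 1
    pair[1::2] -= 1
    order = np.zeros(n, dtype=int)
    flip = rng.random(n_pairs) < 0.5
    order[0::2] = flip.astype(int)
    order[1::2] = 1 - flip.astype(int)
    return gg.PairedBatch(
        truths=rng.integers(0, 21, size=n).astype(float),
        pair_index=pair,
        visit_order=order,
        preds=rng.normal(5, 4, size=n),
    )
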