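import numpy as np
import pytest

from accelpa import GeneratorConfig, generate_cohort

#: Shrunk protocol for fast end-to-end tests: same 13-activity structure,
#: ~12-minute sessions.
SMALL_COHORT_KWARGS = dict(
    n_subjects=4,
    seed=11,
    duration_bounds_min=(0.4, 1.0),
    target_total_min=12.0,
    gap_bounds_s=(5.0, 15.0),
)

#: Reduced training settings for unit tests that only exercise bookkeeping.
FAST_HYPER = dict(restarts=2, max_iter=200)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(GeneratorConfig(**SMALL_COHORT_KWARGS))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_blob_dataset(rng, n_per_class=40, n_features=15, spread=8.0):
    """Three well-separated Gaussian blobs; linearly separable for large
    spread (verified against a linear-classifier oracle in tests)."""
    centers = rng.normal(0.0, 1.0, size=(3, n_features)) * spread
    X = np.vstack([
        centers[c] + rng.normal(0.0, 1.0, size=(n_per_class, n_features))
        for c in range(3)
    ])
    y = np.repeat(np.arange(3), n_per_class)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]
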