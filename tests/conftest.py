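import numpy as np
import pytest

from mozage.io import SampleMetadata, SpectraSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_set(matrix, wavelengths=None, ids=None, ages=None):
    """Small SpectraSet factory for unit tests."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, p = matrix.shape
    if wavelengths is None:
        wavelengths = np.arange(p, dtype=float) + 1000.0
    if ids is None:
        ids = [f"s{i}" for i in range(n)]
    if ages is None:
        ages = [np.nan] * n
    meta = [SampleMetadata(sample_id=s, age_days=a) for s, a in zip(ids, ages)]
    return SpectraSet(wavelengths, matrix, meta)


@pytest.fixture
def small_set(rng):
    return make_set(rng.normal(size=(5, 40)))
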