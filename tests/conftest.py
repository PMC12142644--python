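import numpy as np
import pytest

from secondgram.data import Cohort, PatientRecord
from secondgram.diffusion import make_schedule


class ZeroRng:
    """Noise source that always returns zeros (noiseless limits)."""

    def standard_normal(self, shape=None):
        return np.zeros(shape if shape is not None else ())


@pytest.fixture(scope="session")
def schedule():
    return make_schedule()


@pytest.fixture()
def zero_rng():
    return ZeroRng()


def make_tiny_cohort(n_paired=3, n_unpaired=5, d=4, n_labels=2, seed=0,
                     normalized=True):
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_paired + n_unpaired):
        i1 = rng.uniform(-1, 1, d)
        i2 = rng.uniform(-1, 1, d) if i < n_paired else None
        labels = rng.integers(0, 2, n_labels).astype(float)
        records.append(PatientRecord(f"P{i:03d}", i1, i2, labels))
    ranges = np.column_stack([np.full(d, -1.0), np.full(d, 1.0)])
    return Cohort(records, [f"f{j}" for j in range(d)],
                  [f"l{j}" for j in range(n_labels)],
                  feature_ranges=ranges if normalized else None,
                  is_normalized=normalized)


@pytest.fixture()
def tiny_cohort():
    return make_tiny_cohort()
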