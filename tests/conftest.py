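import numpy as np
import pytest

from tumoroid.spatial_stats import CellTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_random_table():
    """300-cell random pattern with ~10% stem labels on a 200 um field."""
    r = np.random.default_rng(7)
    xy = r.uniform(0, 200, size=(300, 2))
    stem = r.random(300) < 0.1
    stem[:2] = True  # guarantee both labels present
    stem[-2:] = False
    return CellTable(xy[:, 0], xy[:, 1], stem)


@pytest.fixture
def two_blob_table():
    """Two well-separated pure-label blobs (strong positive autocorrelation)."""
    r = np.random.default_rng(3)
    stem_xy = r.normal([30, 30], 3, size=(20, 2))
    diff_xy = r.normal([170, 170], 3, size=(20, 2))
    xy = np.vstack([stem_xy, diff_xy])
    stem = np.array([True] * 20 + [False] * 20)
    return CellTable(xy[:, 0], xy[:, 1], stem)
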