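import numpy as np
import pytest

from mhanet import MHANetSegmenter, default_spec, make_dataset


def records_to_arrays(records):
    X = np.stack([r.image for r in records])
    y = np.stack([r.mask for r in records])
    return X, y


@pytest.fixture(scope="session")
def blob_data_64():
    """Small blob dataset for fast training tests: 8 train + 4 test, 64x64."""
    spec = default_spec("polyp", size=(64, 64))
    return records_to_arrays(make_dataset(8, spec, seed=11)), records_to_arrays(
        make_dataset(4, spec, seed=12)
    )


@pytest.fixture(scope="session")
def fitted_tiny(blob_data_64):
    """A briefly-trained quarter-width model shared across read-only tests."""
    (X, y), _ = blob_data_64
    est = MHANetSegmenter(width_scale=0.25, epochs=3, batch_size=4, seed=0)
    return est.fit(X, y)
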