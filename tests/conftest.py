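import numpy as np
import pandas as pd
import pytest

from treekor.io import EventTable, SampleMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_events(rng):
    """60 events, 4 markers, 3 samples; raw scale."""
    values = rng.gamma(2.0, 20.0, size=(60, 4))
    sample_ids = np.repeat(["s1", "s2", "s3"], 20)
    return EventTable(values=values, marker_names=["CD3", "CD4", "CD8", "CD19"],
                      sample_ids=sample_ids, transformed=False)


@pytest.fixture
def two_group_meta():
    return SampleMetadata(table=pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(1, 9)],
        "condition": ["A"] * 4 + ["B"] * 4,
    }))


def blob_events(rng, centers, n_per_blob=200, sd=0.3, transformed=True):
    """Gaussian blobs on the arcsinh scale, one sample, known structure."""
    centers = np.asarray(centers, dtype=float)
    blocks = [rng.normal(c, sd, size=(n_per_blob, centers.shape[1])) for c in centers]
    values = np.vstack(blocks)
    return EventTable(
        values=values,
        marker_names=[f"M{i}" for i in range(centers.shape[1])],
        sample_ids=np.repeat("s1", len(values)),
        transformed=transformed,
    ), np.repeat(np.arange(len(centers)), n_per_blob)
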