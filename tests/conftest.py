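import numpy as np
import pandas as pd
import pytest

from guildscan.datatypes import FeatureTable, SampleMetadata


@pytest.fixture
def tiny_table() -> FeatureTable:
    """3 samples x 4 ASVs with a mix of zeros and positives."""
    return FeatureTable(
        pd.DataFrame(
            [[5, 0, 3, 2], [1, 2, 0, 7], [0, 7, 1, 2]],
            index=["s1", "s2", "s3"],
            columns=["a1", "a2", "a3", "a4"],
        )
    )


@pytest.fixture
def tiny_metadata() -> SampleMetadata:
    return SampleMetadata(
        pd.DataFrame(
            {
                "group": ["HF", "HF", "HF-UP"],
                "timepoint": ["d0", "d7", "d0"],
                "cage": ["c1", "c1", "c2"],
            },
            index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
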