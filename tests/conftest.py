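import numpy as np
import pandas as pd
import pytest

from complexshare import RankedSamples


@pytest.fixture
def worked_ranking() -> RankedSamples:
    """The 4-sample instance with integer statistics 4 > 3 > 2 > 1."""
    return RankedSamples(
        samples=("s1", "s2", "s3", "s4"),
        statistics=np.array([4.0, 3.0, 2.0, 1.0]),
    )


@pytest.fixture
def small_matrix() -> pd.DataFrame:
    """3 genes x 4 samples, strictly positive."""
    return pd.DataFrame(
        {
            "s1": [3.0, 1.0, 2.0],
            "s2": [8.0, 2.0, 1.0],
            "s3": [1.0, 1.0, 1.0],
            "s4": [6.0, 3.0, 0.5],
        },
        index=pd.Index(["A", "B", "C"], name="gene"),
    )


@pytest.fixture
def gct_text() -> str:
    return (
        "#1.2\n"
        "2\t3\n"
        "Name\tDescription\ts1\ts2\ts3\n"
        "ENSG000001.1\tGENEA\t1.5\t0.0\t2.25\n"
        "ENSG000002.4\tGENEB\t3.0\t4.5\t0.5\n"
    )
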