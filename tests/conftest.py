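import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from npsle import CountMatrix

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_counts():
    """4 genes x 4 samples, two groups, hand-checkable library sizes."""
    counts = pd.DataFrame(
        {
            "s1": [10, 90, 400, 1500],
            "s2": [20, 180, 800, 3000],
            "s3": [5, 50, 445, 1500],
            "s4": [0, 100, 700, 1200],
        },
        index=["geneA", "geneB", "geneC", "geneD"],
    )
    groups = pd.Series(
        {"s1": "control", "s2": "control", "s3": "case", "s4": "case"}
    )
    return CountMatrix(counts, groups)
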