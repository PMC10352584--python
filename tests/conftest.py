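import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20230704)


@pytest.fixture
def small_counts(rng):
    """6 genes x 8 samples of modest NB-ish counts, all positive."""
    x = rng.poisson(rng.gamma(10, 0.1, size=(6, 8)) * 200.0) + 1
    return pd.DataFrame(
        x, index=[f"g{i}" for i in range(6)], columns=[f"s{j}" for j in range(8)]
    )


def make_count_matrix(counts: pd.DataFrame, groups: dict, cell_type="monocyte"):
    """Wrap a plain genes x individuals frame as a replicate-free CountMatrix."""
    from haeseq.normalize import CountMatrix

    samples = pd.DataFrame(
        {
            "individual_id": list(counts.columns),
            "cell_type": cell_type,
            "replicate": 1,
            "group": [groups[c] for c in counts.columns],
        },
        index=pd.Index(counts.columns, name="sample_id"),
    )
    return CountMatrix(counts.copy(), samples)
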