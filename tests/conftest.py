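import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from iraps import ExpressionMatrix

# deterministic property tests: derandomize and keep example counts modest
settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """20 genes x 12 samples, two tissues, log2 scale."""
    genes = [f"g{i}" for i in range(20)]
    samples = [f"s{i}" for i in range(12)]
    values = pd.DataFrame(
        rng.normal(6.0, 1.0, size=(20, 12)), index=genes, columns=samples
    )
    tissues = pd.Series(["breast"] * 6 + ["ovary"] * 6, index=samples)
    return ExpressionMatrix(values, tissues, "log2")
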