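import numpy as np
import pandas as pd
import pytest

from omicsmr import synthdata


@pytest.fixture
def independent_ld():
    """10 mutually uncorrelated SNPs."""
    return synthdata.simulate_ld_matrix(10, rho=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_records(**columns) -> pd.DataFrame:
    """Build a summary-stat table from keyword columns with defaults."""
    n = len(next(iter(columns.values())))
    base = {
        "snp": [f"rs{i + 1}" for i in range(n)],
        "chr": ["1"] * n,
        "pos": list(range(1_000_000, 1_000_000 + 5000 * n, 5000)),
        "ea": ["A"] * n,
        "oa": ["G"] * n,
        "eaf": [0.3] * n,
        "beta": [0.1] * n,
        "se": [0.01] * n,
        "pval": [1e-10] * n,
        "n": [10_000] * n,
    }
    base.update(columns)
    return pd.DataFrame(base)
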