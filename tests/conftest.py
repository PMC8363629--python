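import numpy as np
import pandas as pd
import pytest

from ddx.sumstats import SumstatTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


def make_sumstats(n=20, rng=None, seed=0, alleles=("A", "G"), chrom=1,
                  n_case=5000.0, n_control=5000.0, with_eaf=True):
    """A small valid sumstats table for unit tests."""
    rng = rng or np.random.default_rng(seed)
    beta = rng.normal(0, 0.05, n)
    se = rng.uniform(0.01, 0.05, n)
    from scipy import stats
    df = pd.DataFrame({
        "SNP": [f"rs{i + 1}" for i in range(n)],
        "CHR": chrom,
        "BP": np.arange(1, n + 1) * 1000,
        "A1": alleles[0],
        "A2": alleles[1],
        "BETA": beta,
        "SE": se,
        "P": 2 * stats.norm.sf(np.abs(beta / se)),
        "N": n_case + n_control,
        "N_CASE": n_case,
        "N_CONTROL": n_control,
    })
    if with_eaf:
        df["EAF"] = rng.uniform(0.05, 0.95, n)
    return SumstatTable(df)
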