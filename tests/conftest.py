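import numpy as np
import pandas as pd
import pytest

from pleiocfdr.simulate import SimulationConfig, simulate_sumstats_pair


@pytest.fixture(scope="session")
def small_pair():
    """A deterministic 2,000-SNP paired summary-statistic set with truth labels."""
    cfg = SimulationConfig(n_snps=2_000, seed=11)
    return simulate_sumstats_pair(cfg)


@pytest.fixture
def toy_sumstats():
    """Three clean records in the standard column layout."""
    return pd.DataFrame(
        {
            "rsid": ["rsA", "rsB", "rsC"],
            "chrom": ["1", "1", "2"],
            "pos": [100, 200, 300],
            "effect_allele": ["A", "C", "G"],
            "other_allele": ["G", "T", "A"],
            "effect": [0.1, -0.2, 0.3],
            "pvalue": [0.5, 0.01, 0.9],
        }
    )


def write_tsv(df: pd.DataFrame, path) -> str:
    df.to_csv(path, sep="\t", index=False)
    return str(path)
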