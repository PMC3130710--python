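import numpy as np
import pandas as pd
import pytest

from polyomic import simulate
from polyomic.differential import ExpressionMatrix


@pytest.fixture
def small_config() -> simulate.SimConfig:
    """A fast, fully noisy configuration for smoke-scale runs."""
    return simulate.SimConfig(
        n_proteins=30,
        n_features_transcript=2000,
        n_features_metabolite=60,
        noise_cv=0.2,
        seed=42,
    )


@pytest.fixture
def noiseless_config() -> simulate.SimConfig:
    """Deterministic world: no noise, no outliers, no channel bias."""
    return simulate.SimConfig(
        n_proteins=12,
        peptides_min=4,
        noise_cv=0.0,
        outlier_fraction=0.0,
        max_channel_bias=1.0,
        seed=7,
    )


def toy_matrix(values: dict[str, list[float]], n_ko: int, scale: str = "log2") -> ExpressionMatrix:
    """Features x samples matrix from a dict of rows; first n_ko samples are KO."""
    df = pd.DataFrame.from_dict(values, orient="index", dtype=float)
    n = df.shape[1]
    samples = [f"KO{i+1}" for i in range(n_ko)] + [f"WT{i+1}" for i in range(n - n_ko)]
    df.columns = samples
    groups = pd.Series(["KO"] * n_ko + ["WT"] * (n - n_ko), index=samples)
    return ExpressionMatrix(df, groups, scale=scale)
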