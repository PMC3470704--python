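import numpy as np
import pandas as pd
import pytest

from heterochron.dataset import ExpressionDataset
from heterochron.synthdata import SimulationConfig, generate


@pytest.fixture(scope="session")
def small_null_dataset():
    """Age-related genes, identical curves in both groups (no divergence)."""
    cfg = SimulationConfig(
        n_genes=60, n_per_group=20, frac_age_related=1.0,
        frac_divergent_given_age_related=0.0, seed=101,
    )
    ds, truth = generate(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def planted_shift_dataset():
    """Onset-shift genes, delta = 10 y toward group A, SNR 4, linear."""
    cfg = SimulationConfig(
        n_genes=40, n_per_group=20, frac_age_related=1.0,
        frac_divergent_given_age_related=1.0,
        frac_heterochronic_given_divergent=1.0,
        direction_bias=1.0, shift_years=10.0, heterochrony_mode_mix=1.0,
        trajectory_degree_weights=(0, 1, 0, 0), seed=102,
    )
    ds, truth = generate(cfg)
    return ds, truth


def make_dataset(values, ages, groups):
    values = pd.DataFrame(values)
    sample_ids = values.columns
    return ExpressionDataset(
        values,
        pd.Series(np.asarray(ages, dtype=float), index=sample_ids),
        pd.Series(list(groups), index=sample_ids),
    )
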