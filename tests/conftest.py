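import numpy as np
import pandas as pd
import pytest

from dmscompete import (
    SelectionModel,
    SimulationConfig,
    enumerate_library,
    sample_true_dfe,
    simulate_competition_counts,
)
from dmscompete.orf import random_orf


@pytest.fixture(scope="session")
def small_cfg():
    """Compact competition: 12-codon protein, deep sequencing, clean reads."""
    return SimulationConfig(
        protein_length=12,
        mutagenized_range=(2, 12),
        seed=1,
        depth_per_timepoint=200_000,
        dispensable_c_terminal=0,
    )


@pytest.fixture(scope="session")
def small_orf(small_cfg):
    return random_orf(small_cfg.protein_length, seed=small_cfg.seed)


@pytest.fixture(scope="session")
def small_truth(small_cfg, small_orf):
    lib = enumerate_library(
        small_cfg.protein_length, small_cfg.mutagenized_range, wt_orf=small_orf
    )
    rng = np.random.default_rng(small_cfg.seed)
    sub = lib.variants.sample(120, random_state=0).reset_index(drop=True)
    return sample_true_dfe(small_cfg, sub, rng)


@pytest.fixture(scope="session")
def small_table(small_cfg, small_truth):
    rng = np.random.default_rng(7)
    return simulate_competition_counts(small_truth, small_cfg, rng)


@pytest.fixture(scope="session")
def small_fit(small_table):
    """One shared MCMC run over the small synthetic competition."""
    results = SelectionModel(small_table).fit(samples=2000, seed=3)
    results.normalize()
    return results


def make_selection_frame(s, is_stop=None, is_wt_synonym=None, positions=None):
    """Hand-built selection table for classification-level tests."""
    n = len(s)
    df = pd.DataFrame(
        {
            "position": positions if positions is not None else np.arange(2, n + 2),
            "codon": ["NNN"] * n,
            "aa": ["A"] * n,
            "s_norm": np.asarray(s, dtype=float),
            "is_stop": is_stop if is_stop is not None else [False] * n,
            "is_wt_synonym": is_wt_synonym if is_wt_synonym is not None else [False] * n,
            "is_reference": [False] * n,
        }
    )
    df.loc[df["is_stop"], "aa"] = "*"
    return df
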