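import numpy as np
import pandas as pd
import pytest

from mirdx.simulate import SimulationSpec, gen_expression_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Compact planted cohort reused by clustering/centroid/marker tests."""
    spec = SimulationSpec(n_features=60, n_tumor=20, n_normal=12, n_paired=8,
                          n_planted_up=6, n_planted_down=6,
                          planted_log2fc=2.0, noise_sd=1.0, seed=11)
    return gen_expression_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """Study-shaped cohort (87 vs 22, 4-fold planted markers)."""
    return gen_expression_cohort(SimulationSpec(seed=5))


@pytest.fixture()
def tiny_matrix():
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 3.0, 4.0, 5.0],
         [5.0, 5.0, 5.0, 5.0, 5.0, 5.0],
         [2.0, 1.0, 2.5, 6.0, 5.5, 7.0]],
        index=pd.Index(["f1", "f2", "f3"], name="feature_id"),
        columns=["t1", "t2", "t3", "n1", "n2", "n3"])


@pytest.fixture()
def tiny_groups():
    return pd.Series({"t1": "tumor", "t2": "tumor", "t3": "tumor",
                      "n1": "normal", "n2": "normal", "n3": "normal"})
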