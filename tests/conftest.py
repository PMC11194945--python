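import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import deepcompete as dc

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def balanced_truth() -> pd.DataFrame:
    """Ground truth for the default balanced library (609 prey x 3 baits)."""
    return dc.build_truth(seed=1)


@pytest.fixture(scope="session")
def small_truth() -> pd.DataFrame:
    """Five variants with hand-picked growth rates for solver/identity tests."""
    return pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(5)],
            "true_rate": [0.01, 0.05, 0.10, 0.15, 0.23],
        }
    )


@pytest.fixture(scope="session")
def ideal_assay(balanced_truth):
    """Expected-value, single-plasmid, no-lag simulation: exact recovery regime."""
    cfg = dc.AssayConfig(force_single_plasmid=True, mode="expected", t_lag=0.0, seed=1)
    return dc.simulate_assay(balanced_truth, cfg)


def fit_rates(assay, **kwargs) -> pd.Series:
    """Fitted growth rates of a simulated assay, indexed like its truth table."""
    defaults = {"min_input": 0, "min_output": 0}
    defaults.update(kwargs)
    res = dc.CompetitionGrowthModel.from_simulation(assay, **defaults).fit()
    return res.rates().reindex(assay.truth["variant_id"])
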