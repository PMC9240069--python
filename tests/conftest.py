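import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import omicscore as oc

settings.register_profile(
    "suite", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def planted_metabolomics():
    """Two-group metabolomics simulation with DG planted up at 2 log2 units."""
    cfg = oc.SimulationConfig(
        n_samples_per_group=10,
        n_subpathways=20,
        metabolites_per_subpathway=5,
        planted_effects={"DG": ("up", 2.0)},
        noise_sd=1.0,
        seed=7,
    )
    return oc.simulate_metabolomics(cfg)


@pytest.fixture(scope="session")
def planted_diff(planted_metabolomics):
    matrix, annotation, truth = planted_metabolomics
    diff = oc.differential_table(matrix, oc.ComparisonDesign("group2", "group1"))
    return diff, annotation, truth


def toy_diff_table(records):
    """Build a differential table from (feature, log2FC, p) tuples."""
    df = pd.DataFrame(records, columns=["feature_id", "log2FC", "p"]).set_index("feature_id")
    df["tested"] = True
    df["fdr"] = oc.bh_adjust(df.p.to_numpy())
    df["direction"] = "null"
    sig = df.p <= 0.05
    df.loc[sig & (df.log2FC > 0), "direction"] = "up"
    df.loc[sig & (df.log2FC < 0), "direction"] = "down"
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(0)
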