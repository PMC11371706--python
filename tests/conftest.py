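import numpy as np
import pandas as pd
import pytest

from amoplsnet import FeatureTable, generate_design, generate_feature_table
from amoplsnet.synthetic import EffectSpec


@pytest.fixture
def tiny_table() -> FeatureTable:
    """3 samples x 2 features with one QC."""
    intens = pd.DataFrame(
        [[100.0, 10.0], [200.0, 20.0], [150.0, 15.0]],
        index=["S1", "S2", "QC1"],
        columns=["F1", "F2"],
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["S1", "S2", "QC1"],
            "cultivar": ["CV1", "CV2", "QC"],
            "date": ["D1", "D1", "QC"],
            "extract": ["MeOH"] * 3,
            "ion_mode": ["pos"] * 3,
            "is_qc": [False, False, True],
            "replicate": [1, 1, 1],
        }
    )
    feats = pd.DataFrame({"feature_id": ["F1", "F2"], "mz": [101.1, 202.2], "rt": [1.0, 2.0]})
    return FeatureTable(intens, meta, feats)


@pytest.fixture
def balanced_design() -> pd.DataFrame:
    return generate_design(4, 4, 3, 4, seed=0)


@pytest.fixture
def planted_table(balanced_design):
    """48+4QC x 120 features with cultivar, date and dilution structure."""
    effects = [
        EffectSpec("cultivar", np.arange(0, 30), {"CV1": 1.0, "CV2": 1.0, "CV3": -1.0, "CV4": -1.0},
                   target_rss_share=0.10),
        EffectSpec("date", np.arange(30, 70), {"D1": -1.5, "D2": -0.5, "D3": 0.5, "D4": 1.5},
                   target_rss_share=0.18),
    ]
    table, truth = generate_feature_table(balanced_design, 120, effects, noise_sd=0.2,
                                          dilution_sd=0.3, seed=7)
    return table, truth
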