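import numpy as np
import pandas as pd
import pytest

from spikequant import config as cfgmod
from spikequant import quantify, synthetic


@pytest.fixture(scope="session")
def small_config():
    return cfgmod.CohortConfig(
        cancer_counts={"MM": 12, "CRC": 18, "BRC": 10, "PRC": 10},
        n_plates=2,
        n_proteins=15,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return synthetic.simulate(small_config)


@pytest.fixture(scope="session")
def small_result(small_sim):
    params = quantify.QuantParams(min_proteins=8)
    return quantify.run_quantification(
        small_sim.report, small_sim.panel, small_sim.manifest, params)


@pytest.fixture(scope="session")
def noiseless_sim():
    cfg = cfgmod.noiseless(cfgmod.CohortConfig(
        cancer_counts={"MM": 10, "CRC": 15},
        n_plates=2, n_proteins=15, seed=3))
    return synthetic.simulate(cfg)


def make_transitions(rows):
    """Build a transition report frame from compact dict rows."""
    defaults = {
        "sample_id": "S1", "plate": "P01", "well": "A01",
        "protein": "PROT", "peptide": "PEPTIDEK",
        "precursor_charge": 2, "fragment": "y4", "product_charge": 1,
        "label": "light", "area": 100.0, "rt_min": 10.0,
        "irt_ref": np.nan, "dotp": 0.95,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])
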