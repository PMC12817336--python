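import numpy as np
import pandas as pd
import pytest

from ptcrescue.fcs import EventTable
from ptcrescue.synthetic_data import ReporterCellModel, make_synthetic_cds


@pytest.fixture(scope="session")
def synthetic_cds():
    return make_synthetic_cds(seed=0)


@pytest.fixture()
def clean_model():
    """Noise-free, autofluorescence-free reporter model with equal gains."""
    def _make(theta, **overrides):
        params = dict(
            theta=theta,
            transfected_fraction=0.5,
            autofluor_rfp_mean=0.0,
            autofluor_gfp_mean=0.0,
            autofluor_sd=0.0,
            debris_fraction=0.0,
            noise_cv=0.0,
        )
        params.update(overrides)
        return ReporterCellModel(**params)

    return _make


@pytest.fixture()
def small_events():
    rng = np.random.default_rng(42)
    n = 10
    return EventTable(
        data=pd.DataFrame(
            {
                "FSC": rng.uniform(20_000, 80_000, n),
                "SSC": rng.uniform(10_000, 70_000, n),
                "GFP": rng.uniform(0, 500, n),
                "RFP": rng.uniform(0, 50_000, n),
            }
        ),
        sample_id="fixture-10",
    )
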