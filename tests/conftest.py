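import numpy as np
import pandas as pd
import pytest

from shrinkht import FeatureData, Gaussian, PriorSet
from shrinkht.simulation_eval import DESIGN_ASSAY, DESIGN_TREATMENT


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def make_design_frame(values, feature_id="f1", offsets=None):
    """Six rows in the untreated/treated x 3-assay layout."""
    df = pd.DataFrame(
        {
            "feature_id": feature_id,
            "treatment": DESIGN_TREATMENT,
            "assay": DESIGN_ASSAY,
            "value": values,
        }
    )
    if offsets is not None:
        df["offset"] = offsets
    return df


def make_feature(values, offsets=None, feature_id="f1"):
    if offsets is None:
        offsets = np.zeros(6)
    return FeatureData(
        feature_id, np.asarray(values, float), DESIGN_TREATMENT, DESIGN_ASSAY,
        np.asarray(offsets, float),
    )


@pytest.fixture
def random_feature(rng):
    return make_feature(rng.normal(0.0, 0.5, size=6))


@pytest.fixture
def moderate_priors():
    """Informative priors with all components proper (oracle-friendly scales)."""
    return PriorSet(
        tau2=0.09,
        alpha1=12.0,
        alpha2=1.0,
        treat_prior=Gaussian(-0.2, 0.25),
        intercept_variance=4.0,
    )
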