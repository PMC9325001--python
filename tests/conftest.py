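import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from soctrend import SynthConfig, build_design, generate_network
from soctrend.mixture import SOCMixtureRegression

#: one fixed seed for the shared fixtures; per-test randomness derives from it
SEED = 20180915


@pytest.fixture(scope="session")
def dataset():
    """A default-condition synthetic network (385 plots, 9-year interval)."""
    return generate_network(SynthConfig(seed=SEED))


@pytest.fixture(scope="session")
def design(dataset):
    des, excl = build_design(dataset.plots, dataset.crop_records, dataset.climate["grid_a"])
    assert len(excl) == 0  # generator stays inside the inclusion rules
    return des


@pytest.fixture(scope="session")
def fitted_model(design):
    """One moderate-length fit shared by summary/reporting tests."""
    model = SOCMixtureRegression(n_chains=3, n_iter=6000, burn_in=1500, random_state=SEED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        model.fit(design, design["delta_soc_total"].to_numpy(), groups=design["group_id"].to_numpy())
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
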