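import warnings

import pytest

from bcnet import models
from bcnet.engine import run_ensemble

# the toy network is all-fast in some variants; the resulting time-unit
# warning is expected throughout the suite
warnings.filterwarnings("ignore", message="no slow variables")


@pytest.fixture(scope="session")
def toy():
    return models.toy_rtk_model()


@pytest.fixture(scope="session")
def toy_drugs():
    return models.toy_with_inhibitors()


@pytest.fixture(scope="session")
def bc_model():
    return models.breast_cancer_model()


@pytest.fixture(scope="session")
def er_model():
    return models.er_plus_context_model()


@pytest.fixture(scope="session")
def cancerous(er_model):
    return models.cancerous_ensemble(er_model)


@pytest.fixture(scope="session")
def weights(bc_model):
    return models.outcome_weights(bc_model)


@pytest.fixture(scope="session")
def pi3ki_timecourse(er_model, cancerous):
    """PI3K-inhibition ensemble shared across tests (1000 replicates)."""
    scenario = models.named_protocols(er_model, replicates=1000, seed=11)["pi3ki"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_ensemble(er_model, scenario.protocol)
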