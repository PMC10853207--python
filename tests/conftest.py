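import numpy as np
import pytest

from soilprime.calibrate import LabSetup, lab_observables
from soilprime.mend import MendParams
from soilprime.synth import SynthConfig, make_lab_incubation


@pytest.fixture(scope="session")
def true_params() -> MendParams:
    return MendParams()


@pytest.fixture(scope="session")
def lab_setup() -> LabSetup:
    return LabSetup()


@pytest.fixture(scope="session")
def lab_truth_observables(true_params, lab_setup):
    """Noise-free laboratory observables under the default parameter set."""
    return lab_observables(true_params, lab_setup)


@pytest.fixture(scope="session")
def noisefree_lab():
    """Noise-free synthetic incubation series plus truth bundle."""
    cfg = SynthConfig(seed=11, respiration_noise_cv=0.0)
    return make_lab_incubation(cfg)
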