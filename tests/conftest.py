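import numpy as np
import pytest

from gaitprofile.model import anthropometry_of, build_generic_model, forward_kinematics
from gaitprofile.synth import GaitPattern, STAModel, generate_trial


@pytest.fixture(scope="session")
def model():
    return build_generic_model()


@pytest.fixture(scope="session")
def anthropometry(model):
    return anthropometry_of(model)


@pytest.fixture(scope="session")
def zero_pose_markers(model):
    return forward_kinematics(model, np.zeros(model.n_coordinates))


@pytest.fixture(scope="session")
def clean_trial(model):
    """Three-cycle walking trial without soft-tissue artefact."""
    return generate_trial(model, GaitPattern(), 3, STAModel.zero(), seed=11)


@pytest.fixture(scope="session")
def noisy_trial(model):
    """Three-cycle walking trial with default soft-tissue artefact."""
    return generate_trial(model, GaitPattern(), 3, STAModel(), seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
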