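"""Shared synthetic datasets (generated once per session)."""

import numpy as np
import pytest

from gazeflux.data_model import derive_features
from gazeflux.simulators import AddmParams, ModelSpec, PdgParams
from gazeflux.synthetic import DwellModel, StudyDesign, generate_dataset


@pytest.fixture(scope="session")
def dwell_model():
    return DwellModel()


@pytest.fixture(scope="session")
def addm_study(dwell_model):
    """Published-parameter aDDM study: 5 participants x 100 pairs x 4 reps."""
    design = StudyDesign(n_participants=5, n_trials_per_participant=100, n_reps=4)
    return generate_dataset(
        ModelSpec("addm_mult", AddmParams()), design, dwell_model,
        np.random.default_rng(101),
    )


@pytest.fixture(scope="session")
def addm_features(addm_study):
    return derive_features(addm_study)


@pytest.fixture(scope="session")
def pdg_study(dwell_model):
    """Default-parameter PDG study: 10 participants x 150 trials."""
    design = StudyDesign(n_participants=10, n_trials_per_participant=150)
    return generate_dataset(
        ModelSpec("pdg", PdgParams()), design, dwell_model,
        np.random.default_rng(202),
    )


@pytest.fixture(scope="session")
def pdg_features(pdg_study):
    return derive_features(pdg_study)
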