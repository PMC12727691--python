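import numpy as np
import pytest
from hypothesis import settings

import catmorph as cm
from catmorph.core_io import NeuronMeta, SessionData, StimulusImage, TrialRecord

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_config():
    """Small but complete experiment: 4 identities, both regions, 1 day."""
    exp = cm.ExperimentConfig(n_identities=4, days=2, seed=0)
    return cm.GeneratorConfig(
        experiment=exp,
        n_neurons={"TE": 12, "TEO": 10},
        repeats_per_image=(6, 6),
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_session(tiny_config):
    return cm.simulate_session(tiny_config, 1)


def make_manual_session():
    """Hand-built 5-trial session with 3 TE + 2 TEO neurons.

    Trials: two images of identity 1 (levels 0 and 100), one boundary image
    (identity 2, level 50) plus repeats; counts are small distinct integers
    so row alignment is checkable by eye.
    """
    images = [StimulusImage(1, 0), StimulusImage(1, 100), StimulusImage(2, 50)]
    neurons = [
        NeuronMeta("TE_a", "TE", 1),
        NeuronMeta("TE_b", "TE", 1),
        NeuronMeta("TE_c", "TE", 1),
        NeuronMeta("TEO_a", "TEO", 1),
        NeuronMeta("TEO_b", "TEO", 1),
    ]
    trials = [
        TrialRecord(1, 1, images[0], "first_interval", "correct", np.array([1, 2, 3, 4, 5])),
        TrialRecord(2, 1, images[1], "second_interval", "correct", np.array([6, 7, 8, 9, 10])),
        TrialRecord(3, 1, images[2], "first_interval", "neither", np.array([11, 12, 13, 14, 15])),
        TrialRecord(4, 1, images[0], "second_interval", "error", np.array([16, 17, 18, 19, 20])),
        TrialRecord(5, 1, images[1], "second_interval", "correct", np.array([21, 22, 23, 24, 25])),
    ]
    return SessionData(day=1, neurons=neurons, trials=trials, stimulus_set=images)
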