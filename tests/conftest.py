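import numpy as np
import pytest

import gazedyn as gd
from gazedyn.pipeline import build_trial_measures
from gazedyn.preprocess import exclude_trials


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_experiment():
    """A small mixture-mechanism experiment shared across tests."""
    design = gd.ExperimentDesign(n_participants=4, trials_per_participant=40, seed=11)
    return gd.generate_experiment(design)


@pytest.fixture(scope="session")
def small_measures(small_experiment):
    """Per-trial measures (spread + RQA) for the small experiment."""
    per_trial, kept_fix, filter_report = build_trial_measures(
        small_experiment.trials, small_experiment.fixations, d=103.5
    )
    analyzed, exclusion = exclude_trials(per_trial)
    return {
        "per_trial": per_trial,
        "analyzed": analyzed,
        "kept_fix": kept_fix,
        "filter_report": filter_report,
        "exclusion": exclusion,
    }
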