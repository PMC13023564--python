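import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import wsw

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def face_set():
    """The canonical 2x2x2 sex/race/scar design."""
    return wsw.default_face_set()


@pytest.fixture(scope="session")
def small_cohort(face_set):
    """A 40-participant cohort with the default (realistic) generator."""
    cfg = wsw.GeneratorConfig(seed=7, n_participants=40)
    trials, latents = wsw.simulate_cohort(cfg)
    return trials, latents


@pytest.fixture(scope="session")
def uniform_cohort(face_set):
    """A cohort whose error choices are exactly uniform (all weights 0)."""
    cfg = wsw.GeneratorConfig(
        seed=19, n_participants=200, weight_means=(0, 0, 0), weight_cov=np.zeros((3, 3))
    )
    trials, latents = wsw.simulate_cohort(cfg)
    return trials, latents


def make_trials(rows):
    """Build a trial table from (participant, trial, statement, true, chosen)."""
    frame = pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "trial_index",
            "statement_id",
            "true_face_id",
            "chosen_face_id",
        ],
    )
    frame["correct"] = frame["true_face_id"] == frame["chosen_face_id"]
    return frame
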