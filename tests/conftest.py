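import numpy as np
import pytest

from ontrac.battery import build_registry
from ontrac.trial_engine import simulate_trial
from ontrac.virtual_subject import CohortConfig, VirtualSubject


@pytest.fixture(scope="session")
def registry():
    return build_registry()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_subject(
    *,
    traits=(0.5, 0.5, 0.5),
    lapse=0.02,
    noise_sd=2.5,
    coupling=30.0,
    learning_rate=6e-4,
    subject_id="T001",
):
    names = ("signal_sensitivity", "distractor_suppression", "inhibition")
    return VirtualSubject(
        subject_id=subject_id,
        age_years=12.0,
        medication=False,
        traits=dict(zip(names, traits)),
        lapse_rate=lapse,
        learning_rates={t: learning_rate for t in names},
        symptom_intercept=38.0,
        symptom_noise_sd=noise_sd,
        coupling_strength=coupling,
    )


@pytest.fixture
def subject():
    return make_subject()


@pytest.fixture(scope="session")
def full_dataset():
    """One complete simulated trial with per-trial logs (shared, read-only)."""
    return simulate_trial(config=CohortConfig(), seed=7, trial_detail=True)
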