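import numpy as np
import pytest

from fesgait import synthetic


@pytest.fixture(scope="session")
def default_profile():
    return synthetic.GaitProfile(seed=11)


@pytest.fixture(scope="session")
def noiseless_profile():
    return synthetic.GaitProfile(seed=11, noise_sd_trajectory=0.0)


@pytest.fixture(scope="session")
def noiseless_trial(noiseless_profile):
    """Full synthetic trial with zero trajectory noise (EMG noise still on)."""
    return synthetic.generate_trial(noiseless_profile)


@pytest.fixture(scope="session")
def clean_emg_trial():
    """Trial with clean EMG: no additive noise, no powerline interference."""
    profile = synthetic.GaitProfile(
        seed=3, noise_sd_emg=0.0, powerline_amplitude=0.0
    )
    return synthetic.generate_trial(profile)


@pytest.fixture(scope="session")
def recovery_trials():
    """The seeded speed/cadence grid used for event and parameter recovery."""
    out = []
    for profile in synthetic.recovery_trial_profiles(n_trials=50, master_seed=1):
        trial, events, truth = synthetic.generate_trajectories(profile)
        out.append((profile, trial, events, truth))
    return out
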