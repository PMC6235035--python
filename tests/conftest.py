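import numpy as np
import pandas as pd
import pytest

from serialdep import analysis, simulate


@pytest.fixture(scope="session")
def exp2_trials():
    """One full simulated exp2 run: 6 observers x 2000 trials, sigma 6.7,
    motor noise 6.2, error-minimising weight policy."""
    config = simulate.exp2_config(seed=9)
    obs = simulate.default_observer("exp2")
    return simulate.generate_reproduction_trials(config, obs)


@pytest.fixture(scope="session")
def exp2_kept(exp2_trials):
    kept, _ = analysis.apply_exclusions(exp2_trials)
    return kept


@pytest.fixture()
def toy_trials():
    """Hand-built single-session table with known errors and RTs."""
    stim = [10.0, 20.0, 10.0, 0.0, 170.0]
    resp = [13.0, 20.0, 5.0, 2.0, 1.0]  # errors +3, 0, -5, +2, +11
    return pd.DataFrame({
        "subject": 1,
        "trial_index": np.arange(1, 6),
        "condition": "c",
        "stimulus_orientation_deg": stim,
        "response_orientation_deg": resp,
        "response_time_s": [1.0, 1.2, 0.9, 1.1, 1.3],
    })


def fixed_w_trials(w, sigma=5.0, n=5000, seed=0, motor=0.0,
                   orientations=(-20, -10, 0, 10, 20)):
    """Single-subject session from a fixed-weight observer."""
    config = simulate.ExperimentConfig(
        "exp1", n_subjects=1, trials_per_condition=n,
        orientation_sets={"c": list(map(float, orientations))}, seed=seed)
    obs = simulate.ObserverParams(sigma_by_condition={"c": sigma},
                                  motor_sigma=motor, weight_policy="fixed",
                                  fixed_w=w)
    return simulate.generate_reproduction_trials(config, obs)
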