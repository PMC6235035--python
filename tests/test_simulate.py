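"""Synthetic-experiment generator: designs, observer contract, trial I/O."""

import numpy as np
import pandas as pd
import pytest

from serialdep import simulate
from serialdep.circular import wrap_difference

from conftest import fixed_w_trials


def test_exp1_design_counts():
    config = simulate.exp1_config(seed=1)
    trials = simulate.generate_reproduction_trials(
        config, simulate.default_observer("exp1"))
    assert len(trials) == 6 * 4 * 280
    counts = trials.groupby(["subject", "condition"]).size()
    assert (counts == 280).all()


def test_exp2_design_counts():
    config = simulate.exp2_config(seed=1)
    trials = simulate.generate_reproduction_trials(
        config, simulate.default_observer("exp2"))
    assert len(trials) == 12000


def test_seed_fixes_every_record():
    config = simulate.exp1_config(n_subjects=2, trials_per_condition=30, seed=7)
    obs = simulate.default_observer("exp1")
    a = simulate.generate_reproduction_trials(config, obs)
    b = simulate.generate_reproduction_trials(config, obs)
    pd.testing.assert_frame_equal(a, b)


def test_stimulus_marginals_match_configured_sets():
    config = simulate.exp1_config(n_subjects=2, trials_per_condition=400, seed=3)
    trials = simulate.generate_reproduction_trials(
        config, simulate.default_observer("exp1"))
    for condition, oris in config.orientation_sets.items():
        expected = set(np.mod(oris, 180.0))
        observed = set(trials.loc[trials.condition == condition,
                                  "stimulus_orientation_deg"])
        assert observed == expected


def test_noiseless_veridical_observer_reproduces_stimuli():
    trials = fixed_w_trials(w=0.0, sigma=1e-9, n=200, seed=2)
    err = wrap_difference(trials["response_orientation_deg"].to_numpy(),
                          trials["stimulus_orientation_deg"].to_numpy())
    assert np.max(np.abs(err)) < 1e-6


def test_noiseless_fixed_weight_bias_is_w_times_d():
    trials = fixed_w_trials(w=0.33, sigma=1e-9, n=500, seed=2)
    s = trials["stimulus_orientation_deg"].to_numpy()
    err = wrap_difference(trials["response_orientation_deg"].to_numpy(), s)
    d = wrap_difference(s[:-1], s[1:])
    assert np.allclose(err[1:], 0.33 * d, atol=1e-6)
    assert err[0] == pytest.approx(0.0, abs=1e-6)  # first trial: weight 0


def test_first_trial_unbiased_even_with_optimal_policy():
    config = simulate.ExperimentConfig("exp1", 500, 2, {"c": [0.0, 30.0]}, seed=4)
    obs = simulate.ObserverParams(sigma_by_condition={"c": 1e-9}, motor_sigma=0.0)
    trials = simulate.generate_reproduction_trials(config, obs)
    first = trials[trials.trial_index == 1]
    err = wrap_difference(first["response_orientation_deg"].to_numpy(),
                          first["stimulus_orientation_deg"].to_numpy())
    assert np.max(np.abs(err)) < 1e-6


def test_response_scatter_at_zero_difference_matches_prediction():
    # optimal policy, equal stimuli -> w = 0.5, sd = sqrt(0.5 s^2 + m^2)
    config = simulate.ExperimentConfig("exp1", 1, 20000, {"c": [45.0]}, seed=5)
    obs = simulate.ObserverParams(sigma_by_condition={"c": 6.7}, motor_sigma=6.2)
    trials = simulate.generate_reproduction_trials(config, obs)
    err = wrap_difference(trials["response_orientation_deg"].to_numpy()[1:],
                          trials["stimulus_orientation_deg"].to_numpy()[1:])
    assert err.std() == pytest.approx(np.sqrt(0.5 * 6.7**2 + 6.2**2), abs=0.2)


def test_simulate_rt_contract():
    obs = simulate.ObserverParams(sigma_by_condition={"c": 5.0},
                                  rt_base=1.2, rt_slope=0.005, rt_noise_sd=0.0)
    rng = np.random.default_rng(0)
    assert simulate.simulate_rt(0.0, obs, rng) == pytest.approx(1.2)
    assert simulate.simulate_rt(45.0, obs, rng) == pytest.approx(1.425)
    with pytest.raises(ValueError):
        simulate.simulate_rt(95.0, obs, rng)
    noisy = simulate.ObserverParams(sigma_by_condition={"c": 5.0})
    fast = simulate.simulate_rt(np.zeros(10000), noisy, np.random.default_rng(1))
    slow = simulate.simulate_rt(np.full(10000, 75.0), noisy,
                                np.random.default_rng(2))
    assert np.median(fast) < np.median(slow)


def test_2afc_response_rule_probabilities():
    config = simulate.ExperimentConfig("exp1", 1, 2, {"c": [45.0]}, seed=6)
    obs = simulate.ObserverParams(sigma_by_condition={"c": 6.7})
    delta = 6.7 * np.sqrt(2.0)  # one discrimination s.d. -> Phi(1)
    afc = simulate.generate_2afc_trials(config, obs, deltas=(-delta, delta),
                                        n_per_subject=100000)
    p_pos = afc.loc[afc.delta_deg > 0, "resp_clockwise"].mean()
    p_neg = afc.loc[afc.delta_deg < 0, "resp_clockwise"].mean()
    assert p_pos == pytest.approx(0.8413, abs=0.01)
    assert p_neg == pytest.approx(1 - 0.8413, abs=0.01)
    zero = simulate.generate_2afc_trials(config, obs, deltas=(-1e-12, 1e-12),
                                         n_per_subject=100000)
    assert zero["resp_clockwise"].mean() == pytest.approx(0.5, abs=0.01)


def test_2afc_design_counts_and_validation():
    config = simulate.exp1_config(seed=1)
    afc = simulate.generate_2afc_trials(config, simulate.default_observer("exp1"),
                                        n_per_subject=80)
    assert (afc.groupby("condition").size() == 480).all()
    with pytest.raises(ValueError):
        simulate.generate_2afc_trials(config, simulate.default_observer("exp1"),
                                      deltas=(1.0, 2.0))


def test_trials_roundtrip(tmp_path):
    trials = fixed_w_trials(w=0.2, n=100, seed=8)
    path = tmp_path / "trials.csv"
    simulate.write_trials(path, trials)
    back = simulate.read_trials(path)
    pd.testing.assert_frame_equal(back, trials.reset_index(drop=True))


def test_empty_table_roundtrip(tmp_path):
    empty = pd.DataFrame(columns=simulate.TRIAL_COLUMNS)
    path = tmp_path / "empty.csv"
    simulate.write_trials(path, empty)
    assert len(simulate.read_trials(path)) == 0


def test_invalid_orientation_rejected(tmp_path):
    trials = fixed_w_trials(w=0.0, n=5, seed=8)
    trials.loc[2, "stimulus_orientation_deg"] = 190.0
    path = tmp_path / "bad.csv"
    trials.to_csv(path, index=False)
    with pytest.raises(ValueError, match="line 4"):
        simulate.read_trials(path)


def test_observer_params_validation():
    with pytest.raises(ValueError):
        simulate.ObserverParams(sigma_by_condition={"c": -1.0})
    with pytest.raises(ValueError):
        simulate.ObserverParams(sigma_by_condition={"c": 5.0}, scale_k=2.5)
    with pytest.raises(ValueError):
        simulate.ObserverParams(sigma_by_condition={"c": 5.0},
                                weight_policy="fixed", fixed_w=1.5)
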