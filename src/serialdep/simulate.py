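"""Synthetic orientation-reproduction and 2-AFC experiments.

Emulates two designs:

* **exp1** — 2 × 2 within-subject design crossing base orientation
  (cardinal: -20°..+20° in 10° steps; oblique: 25°..65° in 10° steps) with
  spatial frequency (low / high, which enters only through the sensory
  noise assigned to the condition). Six observers, 280 reproduction trials
  per condition, plus a sequential 2-AFC discrimination task (80 trials per
  observer per condition) to measure reliability.
* **exp2** — orientations all around the clock in 15° steps at a single
  spatial frequency; six observers, ~12 000 trials in total.

The simulated observer draws independent Gaussian internal estimates of the
current and previous stimulus, combines them with a weight given by its
policy (the error-minimising weight at the true inter-stimulus distance,
optionally scaled, or a fixed weight) and adds motor noise at the response
stage. Response times follow an invented linear-in-|d| model with
log-normal noise whose only contractual property is a median minimum at
d = 0; it exists to exercise the RT aggregation stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .circular import wrap_difference, wrap_orientation
from .observer import ReliabilityPair, optimal_weight

__all__ = [
    "ExperimentConfig",
    "ObserverParams",
    "EXP1_ORIENTATION_SETS",
    "EXP2_ORIENTATION_SETS",
    "DEFAULT_SIGMAS_EXP1",
    "exp1_config",
    "exp2_config",
    "default_observer",
    "generate_reproduction_trials",
    "simulate_rt",
    "generate_2afc_trials",
    "write_trials",
    "read_trials",
    "write_2afc",
    "read_2afc",
]

TRIAL_COLUMNS = [
    "subject",
    "trial_index",
    "condition",
    "stimulus_orientation_deg",
    "response_orientation_deg",
    "response_time_s",
]
TWOAFC_COLUMNS = [
    "subject",
    "condition",
    "theta_ref_deg",
    "theta_probe_deg",
    "delta_deg",
    "resp_clockwise",
]

EXP1_ORIENTATION_SETS = {
    "cardinal_high": [-20.0, -10.0, 0.0, 10.0, 20.0],
    "cardinal_low": [-20.0, -10.0, 0.0, 10.0, 20.0],
    "oblique_high": [25.0, 35.0, 45.0, 55.0, 65.0],
    "oblique_low": [25.0, 35.0, 45.0, 55.0, 65.0],
}
EXP2_ORIENTATION_SETS = {"all": [float(t) for t in range(0, 180, 15)]}

# Single-presentation noise per condition. The low-spatial-frequency values
# (5.6° cardinal, 8.2° oblique, mean ~6.7°) anchor the scale; high spatial
# frequency improves discrimination, cardinal beats oblique.
DEFAULT_SIGMAS_EXP1 = {
    "cardinal_high": 4.5,
    "cardinal_low": 5.6,
    "oblique_high": 6.7,
    "oblique_low": 8.2,
}
DEFAULT_SIGMA_EXP2 = 6.7
DEFAULT_MOTOR_SIGMA = 6.2


@dataclass
class ExperimentConfig:
    design: str = "exp1"
    n_subjects: int = 6
    trials_per_condition: int = 280
    orientation_sets: dict = field(default_factory=lambda: dict(EXP1_ORIENTATION_SETS))
    seed: int = 0

    def __post_init__(self):
        if self.design not in ("exp1", "exp2"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_subjects <= 0 or self.trials_per_condition <= 0:
            raise ValueError("counts must be positive")
        if not self.orientation_sets or any(
            len(v) == 0 for v in self.orientation_sets.values()
        ):
            raise ValueError("orientation sets must be non-empty")

    @property
    def conditions(self):
        return list(self.orientation_sets)


@dataclass
class ObserverParams:
    """Generative parameters of the simulated serially-dependent observer."""

    sigma_by_condition: dict = field(default_factory=lambda: dict(DEFAULT_SIGMAS_EXP1))
    motor_sigma: float = DEFAULT_MOTOR_SIGMA
    weight_policy: str = "optimal"  # optimal | scaled | fixed
    scale_k: float = 1.0
    fixed_w: float = 0.0
    use_internal_distance: bool = False
    rt_base: float = 1.2
    rt_slope: float = 0.005
    rt_noise_sd: float = 0.2

    def __post_init__(self):
        if any(s <= 0 for s in self.sigma_by_condition.values()):
            raise ValueError("sigmas must be > 0")
        if self.motor_sigma < 0:
            raise ValueError("motor_sigma must be >= 0")
        if self.weight_policy not in ("optimal", "scaled", "fixed"):
            raise ValueError(f"unknown weight_policy {self.weight_policy!r}")
        if self.weight_policy == "fixed":
            if not 0.0 <= self.fixed_w <= 1.0:
                raise ValueError("fixed_w must lie in [0, 1]")
        # optimal weights never exceed 0.5 for equal reliabilities
        elif not 0.0 <= self.scale_k * 0.5 <= 1.0:
            raise ValueError("scale_k puts reachable weights outside [0, 1]")


def exp1_config(n_subjects: int = 6, trials_per_condition: int = 280, seed: int = 0) -> ExperimentConfig:
    return ExperimentConfig("exp1", n_subjects, trials_per_condition,
                            dict(EXP1_ORIENTATION_SETS), seed)


def exp2_config(n_subjects: int = 6, trials_per_subject: int = 2000, seed: int = 0) -> ExperimentConfig:
    """Experiment-2 design; 6 × 2000 trials reproduce the ~12 000-trial total."""
    return ExperimentConfig("exp2", n_subjects, trials_per_subject,
                            dict(EXP2_ORIENTATION_SETS), seed)


def default_observer(design: str = "exp1", **overrides) -> ObserverParams:
    sigmas = (dict(DEFAULT_SIGMAS_EXP1) if design == "exp1"
              else {"all": DEFAULT_SIGMA_EXP2})
    params = dict(sigma_by_condition=sigmas)
    params.update(overrides)
    return ObserverParams(**params)


def simulate_rt(abs_difference, obs: ObserverParams, rng: np.random.Generator):
    """Response time: (base + slope·|d|) · LogNormal(0, rt_noise_sd)."""
    d = np.asarray(abs_difference, dtype=float)
    if np.any((d < 0) | (d > 90)):
        raise ValueError("abs_difference must lie in [0, 90]")
    mean_rt = obs.rt_base + obs.rt_slope * d
    if obs.rt_noise_sd == 0:
        out = mean_rt
    else:
        out = mean_rt * rng.lognormal(0.0, obs.rt_noise_sd, size=d.shape)
    return out if np.ndim(out) else float(out)


def _weights_for(d, sigma, obs: ObserverParams):
    if obs.weight_policy == "fixed":
        return np.full_like(np.asarray(d, float), obs.fixed_w)
    rel = ReliabilityPair(sigma, sigma)
    return obs.scale_k * np.asarray(optimal_weight(rel, d))


def generate_reproduction_trials(config: ExperimentConfig, obs: ObserverParams,
                                 rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate reproduction trials for every subject × condition session.

    Each subject × condition is one session: stimuli are drawn i.i.d.
    uniformly from the condition's orientation set, and the first trial of
    a session has no predecessor (the observer responds with weight 0).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    frames = []
    n = config.trials_per_condition
    for subject in range(1, config.n_subjects + 1):
        for condition, oris in config.orientation_sets.items():
            try:
                sigma = obs.sigma_by_condition[condition]
            except KeyError:
                raise ValueError(f"no sigma configured for condition {condition!r}")
            s = wrap_orientation(rng.choice(np.asarray(oris, float), size=n))
            x_curr = s + rng.normal(0.0, sigma, size=n)
            x_prev = np.empty(n)
            x_prev[0] = x_curr[0]  # unused: first-trial weight is 0
            x_prev[1:] = s[:-1] + rng.normal(0.0, sigma, size=n - 1)
            d_true = np.zeros(n)
            d_true[1:] = wrap_difference(s[:-1], s[1:])
            d_for_w = (wrap_difference(x_prev, x_curr)
                       if obs.use_internal_distance else d_true)
            w = _weights_for(d_for_w, sigma, obs)
            w[0] = 0.0
            resp = x_curr + w * wrap_difference(x_prev, x_curr)
            if obs.motor_sigma > 0:
                resp = resp + rng.normal(0.0, obs.motor_sigma, size=n)
            resp = wrap_orientation(resp)
            rt = simulate_rt(np.abs(d_true), obs, rng)
            frames.append(pd.DataFrame({
                "subject": subject,
                "trial_index": np.arange(1, n + 1),
                "condition": condition,
                "stimulus_orientation_deg": s,
                "response_orientation_deg": resp,
                "response_time_s": rt,
            }))
    return pd.concat(frames, ignore_index=True)


def generate_2afc_trials(config: ExperimentConfig, obs: ObserverParams,
                         deltas=(-18.0, -12.0, -6.0, 0.0, 6.0, 12.0, 18.0),
                         n_per_subject: int = 80,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate the sequential two-alternative forced-choice task.

    Both presentations receive independent Normal(0, σ) estimate noise, so
    P(probe judged more clockwise | Δ) = Φ(Δ / (σ√2)); the fitted
    cumulative-Gaussian s.d. therefore estimates σ√2, and σ is recovered
    by dividing by √2.
    """
    deltas = np.asarray(deltas, dtype=float)
    if not (np.any(deltas > 0) and np.any(deltas < 0)):
        raise ValueError("deltas must span negative and positive values")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    ref_by_condition = {c: float(np.median(oris))
                        for c, oris in config.orientation_sets.items()}
    frames = []
    for subject in range(1, config.n_subjects + 1):
        for condition in config.conditions:
            sigma = obs.sigma_by_condition[condition]
            theta_ref = ref_by_condition[condition]
            dd = np.resize(np.tile(deltas, n_per_subject // len(deltas) + 1),
                           n_per_subject)
            noise = rng.normal(0.0, sigma, size=(n_per_subject, 2))
            resp = (dd + noise[:, 0] - noise[:, 1]) > 0
            frames.append(pd.DataFrame({
                "subject": subject,
                "condition": condition,
                "theta_ref_deg": theta_ref,
                "theta_probe_deg": wrap_orientation(theta_ref + dd),
                "delta_deg": dd,
                "resp_clockwise": resp.astype(int),
            }))
    return pd.concat(frames, ignore_index=True)


def _validate_trials(df: pd.DataFrame, path="<memory>") -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        return df
    for col, lo, hi in (("stimulus_orientation_deg", 0.0, 180.0),
                        ("response_orientation_deg", 0.0, 180.0)):
        bad = df.index[(df[col] < lo) | (df[col] >= hi) | ~np.isfinite(df[col])]
        if len(bad):
            raise ValueError(
                f"{path}: line {bad[0] + 2}: {col}={df.loc[bad[0], col]!r} "
                f"outside [0, 180)")
    bad = df.index[df["response_time_s"] <= 0]
    if len(bad):
        raise ValueError(f"{path}: line {bad[0] + 2}: non-positive response time")
    return df


def write_trials(path, trials: pd.DataFrame) -> None:
    _validate_trials(trials)
    trials.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return _validate_trials(df, path=str(path))


def write_2afc(path, trials: pd.DataFrame) -> None:
    missing = [c for c in TWOAFC_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"missing columns {missing}")
    trials.to_csv(path, index=False, columns=TWOAFC_COLUMNS)


def read_2afc(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TWOAFC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if not df["resp_clockwise"].isin([0, 1]).all():
        bad = df.index[~df["resp_clockwise"].isin([0, 1])][0]
        raise ValueError(f"{path}: line {bad + 2}: resp_clockwise must be 0/1")
    return df


def config_to_dict(config: ExperimentConfig, obs: ObserverParams) -> dict:
    """Flat serialisable record of a run's resolved configuration."""
    return {"experiment": asdict(config), "observer": asdict(obs)}
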