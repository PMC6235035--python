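"""Connect measured reliabilities to predicted serial-dependence weights.

The ideal-observer model predicts, with zero free parameters, the weight of
the previous stimulus from the measured single-presentation reliability σ:
w_pred = σ² / (2σ² + d_eff²), the optimal weight at an effective
inter-stimulus distance d_eff. With the ±10° fitting window of the 2 × 2
design the measured slope across d ∈ {−10, 0, +10} equals w(10), so
d_eff = 10 by default. A one-parameter variant scales all predictions by a
common factor k; a second one-parameter fit recovers the response-stage
(motor) noise from the per-difference scatter profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .observer import (ReliabilityPair, combined_sd, optimal_weight,
                       prediction_curve, PredictionCurve)
from . import analysis, psychometrics, simulate

__all__ = [
    "FitSummary",
    "predict_weight_from_jnd",
    "r_squared",
    "fit_scaling_factor",
    "MotorNoiseEstimator",
    "fit_motor_noise",
    "predicted_profiles",
    "zero_parameter_experiment",
    "VALIDATION_SIGMAS",
]

# Wide-reliability validation design for end-to-end parameter recovery:
# spans the weight-vs-JND curve while keeping the cardinal < oblique and
# high-SF < low-SF threshold orderings.
VALIDATION_SIGMAS = {
    "cardinal_high": 4.0,
    "cardinal_low": 5.6,
    "oblique_high": 8.2,
    "oblique_low": 11.0,
}

# Exp-2 stimulus-range reliabilities behind the three predicted profile
# curves (cardinal-like, average, oblique-like).
PROFILE_SIGMAS = (5.6, 6.7, 8.3)


@dataclass(frozen=True)
class FitSummary:
    k_hat: float
    r2_zero_param: float
    r2_scaled: float
    motor_sigma_hat: float = float("nan")


def predict_weight_from_jnd(sigma_single: float, d_eff: float = 10.0) -> float:
    """Zero-parameter predicted weight: optimal weight at distance d_eff."""
    if sigma_single <= 0:
        raise ValueError("sigma_single must be > 0")
    return optimal_weight(ReliabilityPair(sigma_single, sigma_single), d_eff)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot; may be negative."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must share length >= 2")
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("R^2 undefined: observed values have zero variance")
    return float(1.0 - np.sum((obs - pred) ** 2) / ss_tot)


def fit_scaling_factor(w_obs, w_pred) -> tuple[float, float]:
    """Least-squares common scaling k of the predictions; returns (k_hat, R²).

    Closed form k = Σ(w_obs·w_pred) / Σ(w_pred²); R² is computed for the
    scaled predictions k·w_pred against the observations.
    """
    w_obs = np.asarray(w_obs, dtype=float)
    w_pred = np.asarray(w_pred, dtype=float)
    denom = np.sum(w_pred**2)
    if denom == 0:
        raise ValueError("degenerate predictor: all predicted weights zero")
    k = float(np.sum(w_obs * w_pred) / denom)
    return k, r_squared(w_obs, k * w_pred)


class MotorNoiseEstimator(BaseEstimator):
    """One-parameter fit of response-stage noise to a scatter profile.

    Predicted scatter at difference d is sqrt(combined_sd(w*(d))² + σ_m²)
    with the optimal weight at d for the supplied sensory noise; σ_m is
    chosen by least squares across difference bins.

    Attributes
    ----------
    motor_sigma_ : float
        Fitted response noise, degrees (>= 0).
    """

    def __init__(self, sigma_single: float = 6.7, upper: float = 45.0):
        self.sigma_single = sigma_single
        self.upper = upper

    def _predicted_perceptual_sd(self, d):
        rel = ReliabilityPair(self.sigma_single, self.sigma_single)
        w = optimal_weight(rel, np.asarray(d, float))
        return combined_sd(rel, w)

    def fit(self, X, y=None) -> "MotorNoiseEstimator":
        """X: profile frame (difference_deg, scatter_deg) or array of d; y: scatter."""
        if isinstance(X, pd.DataFrame):
            d = X["difference_deg"].to_numpy(float)
            obs = X["scatter_deg"].to_numpy(float)
        else:
            d = np.asarray(X, float).ravel()
            obs = np.asarray(y, float).ravel()
        if len(d) < 2:
            raise ValueError("need at least two difference bins")
        base = self._predicted_perceptual_sd(d)

        def loss(sigma_m):
            return np.sum((np.sqrt(base**2 + sigma_m**2) - obs) ** 2)

        if np.all(base >= obs):
            warnings.warn("perceptual scatter already exceeds observations; "
                          "motor noise fixed at 0")
            self.motor_sigma_ = 0.0
            return self
        res = minimize_scalar(loss, bounds=(0.0, self.upper), method="bounded",
                              options={"xatol": 1e-9})
        self.motor_sigma_ = float(res.x) if loss(res.x) <= loss(0.0) else 0.0
        return self


def fit_motor_noise(profile: pd.DataFrame, sigma_single: float) -> float:
    """Functional wrapper over :class:`MotorNoiseEstimator`."""
    return MotorNoiseEstimator(sigma_single).fit(profile).motor_sigma_


def predicted_profiles(sigma_single: float, motor_sigma: float = 0.0,
                       d_grid=None) -> PredictionCurve:
    """Ideal-observer bias/scatter/RMSE curves for one sensory-noise level."""
    return prediction_curve(sigma_single, motor_sigma, d_grid)


def zero_parameter_experiment(seed: int = 0, n_subjects: int = 6,
                              trials_per_condition: int = 280,
                              sigmas: dict | None = None,
                              scale_k: float = 1.0,
                              motor_sigma: float = 0.0,
                              n_2afc_per_subject: int = 80) -> dict:
    """Full simulated test of the zero-parameter weight prediction.

    Simulates the 2 × 2 reproduction experiment and its companion 2-AFC
    reliability task with a serially-dependent ideal observer, estimates
    the weight of the previous stimulus per observer × condition, fits
    psychometric JNDs per condition (observers pooled), predicts weights
    from the fitted reliabilities alone, and summarises the agreement on
    the per-condition means (observers averaged).

    Returns a dict with the per-condition table (w_obs, sigma_single_hat,
    w_pred), the per-subject weight table and a :class:`FitSummary`.
    """
    sigmas = dict(VALIDATION_SIGMAS if sigmas is None else sigmas)
    config = simulate.exp1_config(n_subjects=n_subjects,
                                  trials_per_condition=trials_per_condition,
                                  seed=seed)
    obs = simulate.default_observer("exp1", sigma_by_condition=sigmas,
                                    motor_sigma=motor_sigma,
                                    weight_policy="optimal", scale_k=scale_k)
    trials = simulate.generate_reproduction_trials(config, obs)
    kept, report = analysis.apply_exclusions(trials)
    weights = analysis.estimate_weights_by_group(kept)
    afc = simulate.generate_2afc_trials(config, obs,
                                        n_per_subject=n_2afc_per_subject)
    fits = psychometrics.fit_psychometrics_by_group(afc, by=("condition",))
    cond = (weights.groupby("condition")["w_hat"].mean().rename("w_obs")
            .to_frame().join(fits.set_index("condition")["sigma_single"]))
    cond["w_pred"] = [predict_weight_from_jnd(s) for s in cond["sigma_single"]]
    r2_zero = r_squared(cond["w_obs"], cond["w_pred"])
    k_hat, r2_scaled = fit_scaling_factor(cond["w_obs"], cond["w_pred"])
    return {
        "conditions": cond.reset_index(),
        "subject_weights": weights,
        "filter_report": report,
        "summary": FitSummary(k_hat=k_hat, r2_zero_param=r2_zero,
                              r2_scaled=r2_scaled),
    }
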