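"""Ideal-observer model of serial dependence.

An observer reproducing the orientation of the current stimulus may combine
its noisy sensory estimate with the estimate of the previous stimulus,

    x_hat = (1 - w) * x_curr + w * x_prev ,

trading a reduction of variance against an attractive bias of size ``w * d``
toward the previous stimulus, where ``d`` is the (signed) inter-stimulus
distance on the orientation circle. Minimising the total expected squared
error over the weight ``w`` yields the closed form

    w* = sigma_curr**2 / (sigma_curr**2 + sigma_prev**2 + d**2)

which equals 0.5 for identical, equally reliable stimuli and rolls off as
the stimuli become more different or the previous estimate less reliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .circular import wrap_difference, wrap_orientation

__all__ = [
    "ReliabilityPair",
    "PredictionCurve",
    "IdealObserver",
    "integrate",
    "combined_sd",
    "integration_bias",
    "total_squared_error",
    "optimal_weight",
    "optimal_weight_numeric",
    "bias_peak_distance",
    "prediction_curve",
]


@dataclass(frozen=True)
class ReliabilityPair:
    """Noise standard deviations (degrees) of the two sensory estimates."""

    sigma_curr: float
    sigma_prev: float

    def __post_init__(self):
        for name in ("sigma_curr", "sigma_prev"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")


def _check_weight(w) -> None:
    w = np.asarray(w, dtype=float)
    if np.any((w < 0) | (w > 1) | ~np.isfinite(w)):
        raise ValueError("weight must lie in [0, 1]")


def integrate(x_curr, x_prev, w_prev):
    """Weighted combination of current and previous estimates, on the circle.

    Computed as ``x_curr + w * wrap(x_prev - x_curr)`` so the result never
    jumps across the 0/180 discontinuity; returned wrapped into [0, 180).
    """
    _check_weight(w_prev)
    out = np.asarray(x_curr, float) + np.asarray(w_prev, float) * wrap_difference(
        x_prev, x_curr
    )
    return wrap_orientation(out)


def combined_sd(rel: ReliabilityPair, w_prev) -> float:
    """Standard deviation of the weighted combination, sqrt((1-w)²σc² + w²σp²)."""
    _check_weight(w_prev)
    w = np.asarray(w_prev, dtype=float)
    out = np.sqrt((1.0 - w) ** 2 * rel.sigma_curr**2 + w**2 * rel.sigma_prev**2)
    return out if out.ndim else float(out)


def integration_bias(w_prev, d):
    """Attractive bias w·d (degrees, signed) toward the previous stimulus."""
    _check_weight(w_prev)
    out = np.asarray(w_prev, float) * np.asarray(d, float)
    return out if out.ndim else float(out)


def total_squared_error(rel: ReliabilityPair, w_prev, d):
    """Objective the ideal observer minimises: variance plus squared bias."""
    out = combined_sd(rel, w_prev) ** 2 + np.asarray(integration_bias(w_prev, d)) ** 2
    return out if np.ndim(out) else float(out)


def optimal_weight(rel: ReliabilityPair, d):
    """Closed-form error-minimising weight of the previous stimulus.

    ``w* = σc² / (σc² + σp² + d²)``; lies in (0, 0.5] for equal
    reliabilities, decreasing in |d| and in σ_prev.
    """
    d = np.asarray(d, dtype=float)
    out = rel.sigma_curr**2 / (rel.sigma_curr**2 + rel.sigma_prev**2 + d**2)
    return out if out.ndim else float(out)


def optimal_weight_numeric(rel: ReliabilityPair, d) -> float:
    """Independent numeric oracle: minimise total_squared_error over w ∈ [0, 1].

    Coarse grid scan followed by bounded scalar minimisation; agrees with
    :func:`optimal_weight` to better than 1e-6.
    """
    d = float(d)

    def objective(w):
        return total_squared_error(rel, w, d)

    grid = np.linspace(0.0, 1.0, 201)
    w0 = grid[int(np.argmin(objective(grid)))]
    lo, hi = max(0.0, w0 - 0.01), min(1.0, w0 + 0.01)
    res = minimize_scalar(
        objective, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
    )
    return float(res.x)


def bias_peak_distance(sigma: float) -> float:
    """Distance maximising the optimal-weight bias w*(d)·d (equal reliabilities).

    argmax of σ²·d / (2σ² + d²) over d ≥ 0, i.e. σ·√2.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return float(sigma) * np.sqrt(2.0)


@dataclass
class PredictionCurve:
    """Model-predicted weight / bias / scatter / RMSE versus stimulus change."""

    distances: np.ndarray
    weights: np.ndarray
    biases: np.ndarray
    scatters: np.ndarray
    rmses: np.ndarray
    sigma: float = field(default=np.nan)
    motor_sigma: float = field(default=0.0)

    def __post_init__(self):
        n = len(self.distances)
        for name in ("weights", "biases", "scatters", "rmses"):
            if len(getattr(self, name)) != n:
                raise ValueError("curve arrays must be parallel")


def prediction_curve(sigma: float, motor_sigma: float = 0.0, d_grid=None) -> PredictionCurve:
    """Ideal-observer predictions across a grid of inter-stimulus distances.

    Parameters
    ----------
    sigma : float
        Sensory noise s.d. (degrees) of a single presentation, taken equal
        for the current and previous stimulus.
    motor_sigma : float
        Response-stage noise (degrees) added in quadrature to the
        perceptual scatter.
    d_grid : array-like of degrees, optional
        Signed inter-stimulus distances; defaults to -90..90 in 1° steps.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if motor_sigma < 0 or not np.isfinite(motor_sigma):
        raise ValueError("motor_sigma must be finite and >= 0")
    if d_grid is None:
        d_grid = np.arange(-90.0, 91.0, 1.0)
    d = np.asarray(d_grid, dtype=float)
    if d.size == 0:
        raise ValueError("d_grid must be non-empty")
    rel = ReliabilityPair(sigma, sigma)
    w = optimal_weight(rel, d)
    bias = integration_bias(w, d)
    scatter = np.sqrt(combined_sd(rel, w) ** 2 + motor_sigma**2)
    rmse = np.sqrt(bias**2 + scatter**2)
    return PredictionCurve(d, np.atleast_1d(w), np.atleast_1d(bias),
                           np.atleast_1d(scatter), np.atleast_1d(rmse),
                           sigma=float(sigma), motor_sigma=float(motor_sigma))


class IdealObserver:
    """Ideal observer with fixed sensory and motor noise.

    A light predict-style wrapper over the closed forms above; ``predict``
    returns a :class:`PredictionCurve` over a distance grid.

    Parameters
    ----------
    sigma : float
        Single-presentation sensory noise s.d., degrees.
    motor_sigma : float, default 0
        Response-stage noise s.d., degrees.
    """

    def __init__(self, sigma: float = 6.7, motor_sigma: float = 0.0):
        self.sigma = sigma
        self.motor_sigma = motor_sigma

    def get_params(self, deep: bool = True) -> dict:
        return {"sigma": self.sigma, "motor_sigma": self.motor_sigma}

    def set_params(self, **params) -> "IdealObserver":
        for k, v in params.items():
            if k not in ("sigma", "motor_sigma"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def optimal_weight(self, d):
        return optimal_weight(ReliabilityPair(self.sigma, self.sigma), d)

    def predict(self, d_grid=None) -> PredictionCurve:
        return prediction_curve(self.sigma, self.motor_sigma, d_grid)
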