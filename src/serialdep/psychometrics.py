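"""Cumulative-Gaussian psychometric fits for sequential 2-AFC data.

The proportion of "probe more clockwise" responses as a function of the
orientation difference Δ is fitted with P(Δ) = Φ((Δ − pse) / σ) by maximum
likelihood under the binomial model. One fitted standard deviation is taken
as the just-noticeable difference (JND). Because each 2-AFC trial contains
two independent noisy presentations, the single-presentation reliability is
σ / √2.

No lapse-rate parameter is included (a documented limitation): extreme
response probabilities are modelled exactly by the Gaussian tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm
from sklearn.base import BaseEstimator

__all__ = [
    "PsychometricFit",
    "ReliabilityEstimate",
    "PsychometricFitter",
    "fit_psychometric",
    "reliability_from_fit",
    "fit_psychometrics_by_group",
]

_EPS = 1e-12


@dataclass(frozen=True)
class PsychometricFit:
    pse: float
    sigma_fit: float
    loglik: float
    n_trials: int


@dataclass(frozen=True)
class ReliabilityEstimate:
    sigma_single: float


class PsychometricFitter(BaseEstimator):
    """Maximum-likelihood cumulative-Gaussian psychometric function.

    Deterministic given the data: the optimiser is started from a fixed
    coarse grid of (pse, σ) values and the best converged fit is kept,
    ties broken by log-likelihood then by smaller σ.

    Attributes (after ``fit``)
    --------------------------
    pse_ : float
        50% point, degrees.
    sigma_ : float
        Standard deviation of the fitted cumulative Gaussian (the JND).
    loglik_ : float
        Maximised binomial log-likelihood.
    n_trials_ : int
    """

    def __init__(self, sigma_grid=(1.0, 2.0, 5.0, 10.0, 20.0, 40.0)):
        self.sigma_grid = sigma_grid

    @staticmethod
    def _negloglik(params, delta, k, n):
        pse, log_sigma = params
        sigma = np.exp(log_sigma)
        p = np.clip(norm.cdf((delta - pse) / sigma), _EPS, 1.0 - _EPS)
        return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))

    def fit(self, X, y) -> "PsychometricFitter":
        """Fit to per-trial data: X = deltas (degrees), y = 0/1 responses."""
        delta = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if delta.shape != y.shape:
            raise ValueError("X and y must have the same length")
        tab = pd.DataFrame({"delta": delta, "k": y}).groupby("delta")["k"].agg(
            ["sum", "count"])
        d, k, n = tab.index.to_numpy(), tab["sum"].to_numpy(), tab["count"].to_numpy()
        if len(d) < 2:
            raise ValueError("need responses at >= 2 distinct deltas")
        if k.sum() == 0 or k.sum() == n.sum():
            raise ValueError(
                "degenerate fit: all responses identical; the slope is "
                "unidentifiable")
        span = d.max() - d.min()
        best = None
        for pse0 in np.linspace(d.min(), d.max(), 5):
            for s0 in self.sigma_grid:
                res = minimize(self._negloglik, x0=[pse0, np.log(s0)],
                               args=(d, k, n), method="Nelder-Mead",
                               options={"xatol": 1e-8, "fatol": 1e-10,
                                        "maxiter": 2000})
                cand = (res.fun, np.exp(res.x[1]), res.x)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        negll, sigma, x = best
        if sigma > 100.0 * max(span, 1.0):
            raise ValueError("degenerate fit: psychometric slope ~ 0")
        self.pse_ = float(x[0])
        self.sigma_ = float(sigma)
        self.loglik_ = float(-negll)
        self.n_trials_ = int(n.sum())
        return self

    def predict_proba(self, delta) -> np.ndarray:
        """P('more clockwise') at the given deltas."""
        return norm.cdf((np.asarray(delta, float) - self.pse_) / self.sigma_)


def fit_psychometric(trials: pd.DataFrame) -> PsychometricFit:
    """Fit a 2-AFC trial table (columns delta_deg, resp_clockwise)."""
    f = PsychometricFitter().fit(trials["delta_deg"], trials["resp_clockwise"])
    return PsychometricFit(f.pse_, f.sigma_, f.loglik_, f.n_trials_)


def reliability_from_fit(fit: PsychometricFit) -> ReliabilityEstimate:
    """Single-presentation reliability: σ_fit / √2 (two presentations per trial)."""
    if fit.sigma_fit <= 0:
        raise ValueError("sigma_fit must be > 0")
    return ReliabilityEstimate(fit.sigma_fit / np.sqrt(2.0))


def fit_psychometrics_by_group(trials: pd.DataFrame,
                               by=("subject", "condition")) -> pd.DataFrame:
    """Per-group psychometric fits and derived reliabilities."""
    rows = []
    for keys, grp in trials.groupby(list(by), sort=True):
        fit = fit_psychometric(grp)
        keys = keys if isinstance(keys, tuple) else (keys,)
        rows.append(dict(zip(by, keys)) | {
            "pse": fit.pse, "sigma_fit": fit.sigma_fit,
            "sigma_single": reliability_from_fit(fit).sigma_single,
            "loglik": fit.loglik, "n_trials": fit.n_trials})
    return pd.DataFrame(rows)
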