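"""Empirical serial-dependence pipeline for reproduction data.

Stages: trial exclusions, signed reproduction errors, previous-minus-current
stimulus differences within each session, the bias-versus-difference slope
that estimates the weight of the previous stimulus, and per-difference
profiles of bias, scatter, RMSE and median response time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .circular import wrap_difference

__all__ = [
    "FilterReport",
    "WeightEstimate",
    "apply_exclusions",
    "signed_error",
    "pair_differences",
    "SerialWeightRegressor",
    "estimate_weight",
    "estimate_weights_by_group",
    "profile_by_difference",
]

RT_LIMIT_S = 3.5
ERROR_LIMIT_DEG = 30.0
SESSION_KEYS = ["subject", "condition"]


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_excluded_rt: int
    n_excluded_error: int
    n_kept: int


@dataclass(frozen=True)
class WeightEstimate:
    w_hat: float
    intercept: float
    n_pairs: int
    condition: str = "pooled"
    subject: str = "pooled"


def signed_error(trials: pd.DataFrame):
    """Reproduction error: response minus stimulus, wrapped to (-90, 90].

    Positive means the report was more clockwise than the stimulus.
    """
    return wrap_difference(
        trials["response_orientation_deg"].to_numpy(),
        trials["stimulus_orientation_deg"].to_numpy(),
    )


def apply_exclusions(trials: pd.DataFrame,
                     rt_limit: float = RT_LIMIT_S,
                     error_limit: float = ERROR_LIMIT_DEG):
    """Drop late (> rt_limit s) and wild (> error_limit deg) responses.

    Boundary values are kept. A trial violating both rules is counted under
    the response-time rule. Returns the kept trials and a FilterReport.
    """
    err = np.abs(signed_error(trials))
    late = trials["response_time_s"].to_numpy() > rt_limit
    wild = err > error_limit
    keep = ~(late | wild)
    report = FilterReport(
        n_input=len(trials),
        n_excluded_rt=int(late.sum()),
        n_excluded_error=int((wild & ~late).sum()),
        n_kept=int(keep.sum()),
    )
    return trials.loc[keep].copy(), report


def pair_differences(trials: pd.DataFrame, use_response_abscissa: bool = False) -> pd.DataFrame:
    """Attach signed errors and previous-minus-current differences.

    Trials are ordered by trial_index within each subject × condition
    session; the first trial of each session has no predecessor and is
    dropped. The returned frame adds columns:

    * ``error_deg`` — wrapped signed reproduction error of the current trial;
    * ``d_deg`` — wrapped previous-stimulus minus current-stimulus
      difference (positive: previous more clockwise), or the
      previous-stimulus minus current-response difference when
      ``use_response_abscissa`` is set;
    * ``abs_d_deg`` — its magnitude.
    """
    df = trials.sort_values(SESSION_KEYS + ["trial_index"], kind="stable").copy()
    df["error_deg"] = signed_error(df)
    g = df.groupby(SESSION_KEYS, sort=False)
    prev_stim = g["stimulus_orientation_deg"].shift(1)
    if (g["trial_index"].diff().dropna() <= 0).any():
        raise ValueError("trial_index must increase within each session")
    current = (df["response_orientation_deg"] if use_response_abscissa
               else df["stimulus_orientation_deg"])
    has_prev = prev_stim.notna().to_numpy()
    df = df[has_prev].copy()
    df["d_deg"] = wrap_difference(prev_stim.to_numpy()[has_prev],
                                  current.to_numpy()[has_prev])
    df["abs_d_deg"] = np.abs(df["d_deg"])
    return df


class SerialWeightRegressor(BaseEstimator):
    """Estimate the weight of the previous stimulus from paired trials.

    Fits an ordinary least-squares line (with intercept) of signed
    reproduction error against the previous-minus-current stimulus
    difference, restricted to |d| ≤ ``d_window``; the slope is the weight.
    By default the fit is on the per-difference mean errors (equal weight
    per difference level, e.g. the three points -10/0/+10 of the
    cardinal/oblique designs), not on raw trials.

    Parameters
    ----------
    d_window : float, default 10
        Half-width (degrees) of the difference window, inclusive.
    on_means : bool, default True
        Fit per-difference mean errors instead of raw trials.
    use_response_abscissa : bool, default False
        Window and abscissa from the previous-stimulus-minus-current-
        response difference instead of the stimulus–stimulus one.

    Attributes
    ----------
    weight_ : float
        Fitted slope, the loading of the previous orientation.
    intercept_ : float
        Orientation-independent response bias, degrees.
    n_pairs_ : int
        Number of trial pairs inside the window.
    """

    def __init__(self, d_window: float = 10.0, on_means: bool = True,
                 use_response_abscissa: bool = False):
        self.d_window = d_window
        self.on_means = on_means
        self.use_response_abscissa = use_response_abscissa

    def fit(self, trials: pd.DataFrame, y=None) -> "SerialWeightRegressor":
        if {"d_deg", "error_deg"}.issubset(trials.columns):
            paired = trials
        else:
            paired = pair_differences(
                trials, use_response_abscissa=self.use_response_abscissa)
        sel = paired[np.abs(paired["d_deg"]) <= self.d_window]
        if len(sel) == 0 or sel["d_deg"].nunique() < 2:
            raise ValueError(
                "need at least two distinct difference values inside the window")
        if self.on_means:
            pts = sel.groupby("d_deg")["error_deg"].mean()
            x, y_ = pts.index.to_numpy(), pts.to_numpy()
        else:
            x, y_ = sel["d_deg"].to_numpy(), sel["error_deg"].to_numpy()
        slope, intercept = np.polyfit(x, y_, 1)
        self.weight_ = float(slope)
        self.intercept_ = float(intercept)
        self.n_pairs_ = int(len(sel))
        return self

    def predict(self, d) -> np.ndarray:
        """Predicted mean error at the given differences."""
        return self.weight_ * np.asarray(d, float) + self.intercept_


def estimate_weight(trials: pd.DataFrame, d_window: float = 10.0,
                    on_means: bool = True,
                    use_response_abscissa: bool = False) -> WeightEstimate:
    """Functional wrapper over :class:`SerialWeightRegressor`."""
    reg = SerialWeightRegressor(d_window, on_means, use_response_abscissa).fit(trials)
    return WeightEstimate(reg.weight_, reg.intercept_, reg.n_pairs_)


def estimate_weights_by_group(trials: pd.DataFrame, d_window: float = 10.0,
                              by=SESSION_KEYS) -> pd.DataFrame:
    """Per-group weight estimates (default: per subject × condition)."""
    paired = pair_differences(trials)
    rows = []
    for keys, grp in paired.groupby(list(by), sort=True):
        est = estimate_weight(grp, d_window=d_window)
        keys = keys if isinstance(keys, tuple) else (keys,)
        rows.append(dict(zip(by, keys)) | {
            "w_hat": est.w_hat, "intercept": est.intercept,
            "n_pairs": est.n_pairs})
    return pd.DataFrame(rows)


def profile_by_difference(trials: pd.DataFrame, mode: str = "signed") -> pd.DataFrame:
    """Bias / scatter / RMSE / median-RT profile across difference levels.

    Groups paired trials by the exact previous-minus-current difference
    (signed mode) or its magnitude (absolute mode; errors are folded by the
    sign of the difference so attraction toward the previous stimulus stays
    positive). Per bin: mean bias, scatter (population s.d. of errors about
    the bin mean, so rmse² = bias² + scatter² exactly), RMSE about the true
    stimulus, median response time and trial count.
    """
    if mode not in ("signed", "absolute"):
        raise ValueError(f"mode must be 'signed' or 'absolute', got {mode!r}")
    if {"d_deg", "error_deg"}.issubset(trials.columns):
        paired = trials.copy()
    else:
        paired = pair_differences(trials)
    if len(paired) == 0:
        warnings.warn("no paired trials; empty profile")
        return pd.DataFrame(columns=["difference_deg", "mean_bias_deg",
                                     "scatter_deg", "rmse_deg",
                                     "median_rt_s", "n"])
    if mode == "absolute":
        key = paired["abs_d_deg"]
        err = paired["error_deg"] * np.where(paired["d_deg"] < 0, -1.0, 1.0)
    else:
        key = paired["d_deg"]
        err = paired["error_deg"]
    out = []
    for d_val, idx in err.groupby(key.to_numpy()).groups.items():
        e = err.loc[idx].to_numpy()
        out.append({
            "difference_deg": float(d_val),
            "mean_bias_deg": float(e.mean()),
            "scatter_deg": float(e.std(ddof=0)),
            "rmse_deg": float(np.sqrt(np.mean(e**2))),
            "median_rt_s": float(paired.loc[idx, "response_time_s"].median()),
            "n": int(len(e)),
        })
    return pd.DataFrame(out).sort_values("difference_deg", ignore_index=True)
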