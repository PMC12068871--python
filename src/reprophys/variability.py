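"""Firing-rate variability versus unit location and waveform shape.

Identifies outlier (high-firing) neurons, compares feature distributions
between neuron groups with Bonferroni-corrected KS tests, and fits the
five-feature ordinary-least-squares model quantifying how much
session-averaged firing-rate variance is explained by spatial position
(x, y, z), spike amplitude and peak-to-trough duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "FEATURES",
    "RegressionResult",
    "find_outliers",
    "compare_feature_distributions",
    "variance_regression",
]

#: The five per-neuron predictors.
FEATURES = ("x", "y", "z", "amplitude", "ptt_duration")


@dataclass
class RegressionResult:
    coefficients: pd.Series   # per-feature slope, original units
    p_values: pd.Series       # t-based
    intercept: float
    r_squared: float          # unadjusted
    n: int


def find_outliers(rates, frac: float = 0.15) -> np.ndarray:
    """Neurons whose absolute deviation from the median firing rate
    exceeds ``frac`` of the firing-rate range.

    A zero range (all rates equal) yields an empty mask. With only two
    distinct rates both can be flagged — a documented degeneracy of the
    range-based rule.
    """
    rates = np.asarray(rates, dtype=float)
    if len(rates) < 2:
        raise ValueError("need at least two neurons")
    rng_ = np.ptp(rates)
    if rng_ == 0:
        return np.zeros(len(rates), dtype=bool)
    return np.abs(rates - np.median(rates)) > frac * rng_


def compare_feature_distributions(
    table: pd.DataFrame,
    mask: np.ndarray,
    features=FEATURES,
) -> pd.DataFrame:
    """Per-feature two-sample KS tests between masked and unmasked neurons,
    Bonferroni-corrected over the features.

    Returns a frame with the KS statistic, raw and corrected p-values, and
    significance stars at corrected p < 0.05 / < 0.01. Features where
    either group has fewer than two members come back NaN (undetermined).
    """
    mask = np.asarray(mask, dtype=bool)
    rows = []
    n_tests = len(features)
    for feat in features:
        a = table.loc[mask, feat].to_numpy(dtype=float)
        b = table.loc[~mask, feat].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            rows.append(
                {"feature": feat, "ks_stat": np.nan, "p_raw": np.nan,
                 "p_corrected": np.nan, "significant_05": False, "significant_01": False}
            )
            continue
        res = stats.ks_2samp(a, b)
        p_corr = min(1.0, res.pvalue * n_tests)
        rows.append(
            {
                "feature": feat,
                "ks_stat": float(res.statistic),
                "p_raw": float(res.pvalue),
                "p_corrected": float(p_corr),
                "significant_05": bool(p_corr < 0.05),
                "significant_01": bool(p_corr < 0.01),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def variance_regression(
    table: pd.DataFrame,
    response: str = "session_mean_rate",
    features=FEATURES,
) -> RegressionResult:
    """OLS of session-averaged firing rate on the five neuron features.

    Predictors are standardized internally for numerical conditioning and
    the coefficients reported back in original units — numerically
    equivalent to raw OLS without regularization. Reports the unadjusted
    coefficient of determination. Raises on rank-deficient predictors,
    naming the collinear columns.
    """
    n = len(table)
    if n <= len(features) + 1:
        raise ValueError("need more rows than predictors")
    X = table.loc[:, list(features)].to_numpy(dtype=float)
    y = table[response].to_numpy(dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("regression inputs must not contain missing values")

    sd = X.std(axis=0)
    degenerate = [f for f, s in zip(features, sd) if s == 0]
    if degenerate:
        raise ValueError(f"collinear (constant) predictor columns: {degenerate}")
    Xs = (X - X.mean(axis=0)) / sd
    if np.linalg.matrix_rank(Xs) < Xs.shape[1]:
        # Identify offending columns: those whose removal restores full rank.
        collinear = [
            f
            for i, f in enumerate(features)
            if np.linalg.matrix_rank(np.delete(Xs, i, axis=1)) == np.linalg.matrix_rank(Xs)
        ]
        raise ValueError(f"rank-deficient predictors; collinear columns: {collinear}")

    fit = sm.OLS(y, sm.add_constant(Xs)).fit()
    beta_std = fit.params[1:]
    beta = beta_std / sd
    intercept = float(fit.params[0] - np.sum(beta * X.mean(axis=0)))
    return RegressionResult(
        coefficients=pd.Series(beta, index=list(features)),
        p_values=pd.Series(fit.pvalues[1:], index=list(features)),
        intercept=intercept,
        r_squared=float(fit.rsquared),
        n=n,
    )
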