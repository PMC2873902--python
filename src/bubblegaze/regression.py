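"""Variance partitioning of empirical salience.

The final quantification regresses log empirical salience on the log of
the three predictors — stimulus-dependent (feature) salience, bubble
information, and spatial-bias salience — per task.  Reported are the
pairwise Pearson correlations with t-tests, the multivariate OLS fit (R^2
and overall F-test), and semi-partial correlations: the correlation of the
outcome with the residual of one predictor after regressing it on the
others, whose square is that predictor's unique contribution to R^2.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

LOG_FLOOR = 1e-6

PREDICTORS = ("feature", "information", "spatial")


def log_transform(values, floor: float = LOG_FLOOR) -> np.ndarray:
    """Natural log of max(value, floor); negative inputs are rejected.

    The floor keeps zero saliences/informations finite; correlations are
    invariant to the log base.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("log transform requires nonnegative values")
    return np.log(np.maximum(v, floor))


def correlation_tests(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-test on n - 2 df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def multivariate_regression(
    X: pd.DataFrame | np.ndarray, y
) -> tuple[float, float, np.ndarray]:
    """OLS of y on X with intercept: (R^2, overall F-test p, coefficients).

    Coefficients are returned without the intercept, in column order.
    """
    Xa = np.asarray(X, float)
    ya = np.asarray(y, float)
    if Xa.shape[0] <= Xa.shape[1] + 1:
        raise ValueError("need more observations than predictors + 1")
    model = sm.OLS(ya, sm.add_constant(Xa)).fit()
    return float(model.rsquared), float(model.f_pvalue), model.params[1:]


def semipartial_correlations(
    X: pd.DataFrame | np.ndarray, y
) -> pd.DataFrame:
    """Semi-partial correlation of each predictor with the outcome.

    Predictor j is regressed (with intercept) on the other predictors; the
    residual is correlated with y.  sr_j^2 equals R^2(full) minus R^2 of
    the model without j.  Significance comes from the added-last t-test
    t = sr * sqrt(n - k - 1) / sqrt(1 - R^2_full) on n - k - 1 df.
    """
    Xa = np.asarray(X, float)
    ya = np.asarray(y, float)
    names = (
        list(X.columns)
        if isinstance(X, pd.DataFrame)
        else [f"x{j}" for j in range(Xa.shape[1])]
    )
    n, k = Xa.shape
    r2_full, _, _ = multivariate_regression(Xa, ya)
    rows = []
    for j in range(k):
        others = np.delete(Xa, j, axis=1)
        resid = sm.OLS(Xa[:, j], sm.add_constant(others)).fit().resid
        if np.std(resid) == 0:
            raise ValueError(f"predictor {names[j]!r} is collinear with the others")
        sr = float(stats.pearsonr(resid, ya)[0])
        df = n - k - 1
        denom = max(1.0 - r2_full, 1e-12)
        t = sr * math.sqrt(df) / math.sqrt(denom)
        p = 2.0 * stats.t.sf(abs(t), df)
        rows.append((names[j], sr, float(p)))
    return pd.DataFrame(rows, columns=["predictor", "sr", "p"])


def build_predictor_matrix(
    empirical: pd.Series,
    feature: pd.Series,
    information: pd.Series,
    spatial: pd.Series,
    floor: float = LOG_FLOOR,
) -> pd.DataFrame:
    """Align the four per-bubble measures on their common bubbles and log
    transform them.  Columns: feature, information, spatial, empirical."""
    df = pd.concat(
        {
            "feature": feature,
            "information": information,
            "spatial": spatial,
            "empirical": empirical,
        },
        axis=1,
        join="inner",
    ).dropna()
    if df.empty:
        raise ValueError("no bubbles shared by all four measures")
    return df.apply(lambda c: log_transform(c, floor))


def salience_regression(matrix: pd.DataFrame) -> pd.DataFrame:
    """The full correlation analysis of one task on an aligned log matrix.

    Returns one row per predictor with pairwise r/p and semi-partial sr/p,
    plus the model-level R^2 and F-test p repeated on each row.
    """
    X = matrix[list(PREDICTORS)]
    y = matrix["empirical"]
    r2, fp, coefs = multivariate_regression(X, y)
    sp = semipartial_correlations(X, y).set_index("predictor")
    rows = []
    for name in PREDICTORS:
        r, p = correlation_tests(matrix[name], y)
        rows.append(
            {
                "predictor": name,
                "r": r,
                "r_p": p,
                "sr": sp.loc[name, "sr"],
                "sr_p": sp.loc[name, "p"],
                "coef": coefs[list(PREDICTORS).index(name)],
                "r_squared": r2,
                "f_p": fp,
            }
        )
    return pd.DataFrame(rows)


def stars(p: float) -> str:
    """Significance marks: ** for p<0.01, * for p<0.05."""
    return "**" if p < 0.01 else "*" if p < 0.05 else ""


def results_table(per_task: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-task regression frames into one results table with
    significance stars, mirroring the layout of the headline analysis."""
    out = []
    for task, df in per_task.items():
        d = df.copy()
        d.insert(0, "task", task)
        d["r_stars"] = d["r_p"].map(stars)
        d["sr_stars"] = d["sr_p"].map(stars)
        d["r2_stars"] = d["f_p"].map(stars)
        out.append(d)
    return pd.concat(out, ignore_index=True)
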