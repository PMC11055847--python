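"""Regression machinery: per-item trend models, variable selection across
two questionnaire administrations, stepwise screening of potassium-source
food groups, and derivation of the empirical prediction weights.

Items enter the trend models one at a time (each adjusted for six
characteristics); the final prediction equation fits all selected items
simultaneously, optionally together with sex, age, BMI and
antihypertensive-medication use.  Alcohol frequency and smoking are trend
adjusters only and never enter the prediction equation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, DomainError, SingularDesignError

#: adjusters of the per-item trend models
TREND_ADJUSTERS = ("sex", "age", "bmi", "alcohol", "smoker", "htn_med")
#: characteristics that may enter the prediction equation
EQUATION_CHARACTERISTICS = ("sex", "age", "bmi", "htn_med")

OUTCOME_COLUMNS = {"sodium_mg": "na_mg_per_day", "nak_mol": "nak_mol"}


@dataclass
class OLSFit:
    """Least-squares fit with classical (homoskedastic) inference."""

    names: list[str]
    params: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    df_resid: int
    sigma2: float

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])


@dataclass
class RegressionResult:
    """Trend of one ordinal item on the outcome, adjusted for covariates."""

    item: str
    slope: float
    se: float
    p_trend: float
    covariates: list[str]
    n: int


@dataclass
class PredictionEquation:
    """Empirical-weight score: intercept + sum(coefficient * coded value)."""

    outcome: str  # sodium_mg | nak_mol
    intercept: float
    coefficients: dict[str, float]
    includes_characteristics: bool
    coding_map_version: int = 1

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PredictionEquation":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns that do not increase the incremental rank (span of earlier ones)."""
    bad, rank = [], 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, : j + 1])
        if r == rank:
            bad.append(names[j])
        rank = r
    return bad


def fit_ols(y, X, names: Sequence[str] | None = None) -> OLSFit:
    """Ordinary least squares with unbiased residual variance and t-tests.

    ``X`` must already contain the intercept column.  Rank deficiency
    raises :class:`SingularDesignError` naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise DomainError("X must be 2-D with one row per element of y")
    n, p = X.shape
    if n <= p:
        raise DomainError(f"need more observations ({n}) than parameters ({p})")
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    if np.linalg.matrix_rank(X) < p:
        raise SingularDesignError(_collinear_columns(X, names))
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = n - p
    sigma2 = float(resid @ resid) / df_resid
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(sigma2 * np.diag(XtX_inv), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    return OLSFit(names, beta, se, pvals, df_resid, sigma2)


def _alcohol_dummies(frame: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    levels = [2, 3, 4]  # reference: none (1)
    cols = [(frame["alcohol"].to_numpy() == lv).astype(float) for lv in levels]
    return np.column_stack(cols), [f"alcohol_{lv}" for lv in levels]


def _trend_design(frame: pd.DataFrame, item: str) -> tuple[np.ndarray, list[str]]:
    alc, alc_names = _alcohol_dummies(frame)
    X = np.column_stack([
        np.ones(len(frame)),
        frame[item].to_numpy(dtype=float),
        frame["sex"].to_numpy(dtype=float),
        frame["age"].to_numpy(dtype=float),
        frame["bmi"].to_numpy(dtype=float),
        alc,
        frame["smoker"].to_numpy(dtype=float),
        frame["htn_med"].to_numpy(dtype=float),
    ])
    names = ["intercept", item, "sex", "age", "bmi", *alc_names, "smoker", "htn_med"]
    return X, names


def per_item_trend(frame: pd.DataFrame, item: str, outcome: str) -> RegressionResult:
    """Trend slope of one ordinal item, adjusted for the six characteristics.

    ``outcome`` is an outcome key (``sodium_mg``/``nak_mol``) or a column
    name.  A constant item raises :class:`SingularDesignError`; a constant
    outcome returns slope 0 with a degenerate-variance warning.
    """
    ycol = OUTCOME_COLUMNS.get(outcome, outcome)
    data = frame.dropna(subset=[ycol])
    y = data[ycol].to_numpy(dtype=float)
    if np.ptp(data[item].to_numpy(dtype=float)) == 0:
        raise SingularDesignError([item])
    X, names = _trend_design(data, item)
    if np.ptp(y) == 0:
        warnings.warn(f"degenerate outcome variance for item '{item}'", stacklevel=2)
        return RegressionResult(item, 0.0, np.nan, 1.0, list(TREND_ADJUSTERS), len(y))
    fit = fit_ols(y, X, names)
    j = names.index(item)
    return RegressionResult(item, float(fit.params[j]), float(fit.se[j]),
                            float(fit.pvalues[j]), list(TREND_ADJUSTERS), len(y))


def select_variables(results_ffq1: Sequence[RegressionResult],
                     results_ffq2: Sequence[RegressionResult],
                     alpha: float = 0.05) -> list[str]:
    """Items with a significant trend in BOTH administrations.

    Order follows ``results_ffq1``; both lists must cover the same items.
    """
    p1 = {r.item: r.p_trend for r in results_ffq1}
    p2 = {r.item: r.p_trend for r in results_ffq2}
    if set(p1) != set(p2):
        raise DomainError("FFQ1 and FFQ2 trend results cover different item sets")
    return [r.item for r in results_ffq1 if p1[r.item] < alpha and p2[r.item] < alpha]


@dataclass
class StepwiseResult:
    selected: list[str]
    fit: OLSFit | None


def stepwise_select(X: pd.DataFrame, y, entry: float = 0.05, stay: float = 0.05,
                    max_iter: int = 100) -> StepwiseResult:
    """Bidirectional p-value stepwise selection over candidate columns.

    Forward step adds the candidate with the smallest partial p-value if it
    is below ``entry``; backward step removes included variables whose
    p-value exceeds ``stay``; iterate to stability.
    """
    y = np.asarray(y, dtype=float)
    candidates = list(X.columns)
    included: list[str] = []

    def fit_model(cols: list[str]) -> OLSFit:
        M = np.column_stack([np.ones(len(y))] + [X[c].to_numpy(dtype=float) for c in cols])
        return fit_ols(y, M, ["intercept", *cols])

    for _ in range(max_iter):
        changed = False
        # forward
        best_p, best_c = None, None
        for c in candidates:
            if c in included:
                continue
            try:
                f = fit_model(included + [c])
            except SingularDesignError:
                continue
            p = f.pvalues[f.names.index(c)]
            if best_p is None or p < best_p:
                best_p, best_c = p, c
        if best_c is not None and best_p < entry:
            included.append(best_c)
            changed = True
        # backward
        while included:
            f = fit_model(included)
            pvals = {c: f.pvalues[f.names.index(c)] for c in included}
            worst = max(pvals, key=pvals.get)
            if pvals[worst] > stay:
                included.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break
    if not included:
        return StepwiseResult([], None)
    return StepwiseResult(included, fit_model(included))


def derive_weights(frame: pd.DataFrame, selected_items: Sequence[str], outcome: str,
                   include_characteristics: bool = False,
                   coding_map_version: int = 1) -> PredictionEquation:
    """Empirical weights: one simultaneous fit of all selected variables.

    ``frame`` holds per-person coded items and the outcome column; with
    ``include_characteristics`` the design gains sex, age, BMI and
    antihypertensive-medication use.
    """
    if not selected_items:
        raise DegenerateDataError("no selected items; cannot derive weights")
    ycol = OUTCOME_COLUMNS.get(outcome, outcome)
    data = frame.dropna(subset=[ycol])
    variables = list(selected_items)
    if include_characteristics:
        variables += list(EQUATION_CHARACTERISTICS)
    X = np.column_stack([np.ones(len(data))]
                        + [data[v].to_numpy(dtype=float) for v in variables])
    fit = fit_ols(data[ycol].to_numpy(dtype=float), X, ["intercept", *variables])
    return PredictionEquation(
        outcome=outcome if outcome in OUTCOME_COLUMNS else ycol,
        intercept=float(fit.params[0]),
        coefficients={v: float(c) for v, c in zip(variables, fit.params[1:])},
        includes_characteristics=include_characteristics,
        coding_map_version=coding_map_version,
    )


def trend_table(frame: pd.DataFrame, items: Sequence[str], outcome: str) -> pd.DataFrame:
    """Trend results for a list of items as a tidy frame."""
    rows = []
    for item in items:
        r = per_item_trend(frame, item, outcome)
        rows.append({"item": r.item, "slope": r.slope, "se": r.se,
                     "p_trend": r.p_trend, "n": r.n})
    return pd.DataFrame(rows)
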