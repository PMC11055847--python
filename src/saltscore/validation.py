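"""Split-sample validation of the prediction equations.

Participants are split into development and validation halves balanced on
sex, top quartile of questionnaire sodium, and taste preference.  The
development-group equation is scored on the validation group and compared
to measured mean urinary values via Spearman correlation, deattenuated as

    adjusted CC = observed CC * sqrt(1 + lambda_x / n)

where lambda_x is the within- to between-person variance ratio of the
daily measurements and n the number of urine collections averaged.  The
ratio is estimated per outcome and stratum by the one-way random-effects
(ANOVA method-of-moments) variance decomposition.  Agreement is described
by Bland-Altman statistics including a proportional-bias slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (DegenerateDataError, DomainError, PredictionError)
from .ffq import energy_adjust, questionnaire_nak_ratio
from .modeling import PredictionEquation


def balanced_split(frame: pd.DataFrame, seed: int,
                   strata_cols: Sequence[str] = ("sex", "top_na_quartile",
                                                 "taste_preference")) -> pd.DataFrame:
    """Stratified random halves: within every stratum the two groups
    differ by at most one member.

    Members of each stratum are shuffled with the seed and alternated
    between the groups, with a random starting group per stratum.
    """
    if frame.empty:
        raise DomainError("cannot split an empty cohort")
    for c in strata_cols:
        if c not in frame.columns:
            raise DomainError(f"stratum column '{c}' missing")
    rng = np.random.default_rng(seed)
    group = pd.Series(index=frame.index, dtype=object)
    for _, stratum in frame.groupby(list(strata_cols), sort=True):
        idx = stratum.index.to_numpy()
        perm = rng.permutation(len(idx))
        start = int(rng.integers(2))
        labels = np.where((np.arange(len(idx)) + start) % 2 == 0,
                          "development", "validation")
        group.loc[idx[perm]] = labels
    out = frame[["participant_id", *strata_cols]].copy()
    out["group"] = group
    return out


def predict(equation: PredictionEquation, record: Mapping) -> float:
    """Score one record: intercept + sum(coefficient * coded value)."""
    total = equation.intercept
    for var, coef in equation.coefficients.items():
        if var not in record or pd.isna(record[var]):
            raise PredictionError(var)
        total += coef * float(record[var])
    return float(total)


def predict_frame(equation: PredictionEquation, frame: pd.DataFrame) -> np.ndarray:
    """Vectorized scoring of a coded table."""
    total = np.full(len(frame), equation.intercept)
    for var, coef in equation.coefficients.items():
        if var not in frame.columns:
            raise PredictionError(var)
        total = total + coef * frame[var].to_numpy(dtype=float)
    return total


def spearman_cc(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DomainError("need two equal-length vectors with >= 3 elements")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


@dataclass
class LambdaEstimate:
    lambda_x: float
    n_collections: float
    sigma2_within: float
    sigma2_between: float
    clamped: bool


def estimate_lambda(days: pd.DataFrame, value_col: str,
                    id_col: str = "participant_id",
                    floor: float = 1e-6, log_scale: bool = False) -> LambdaEstimate:
    """Within/between variance ratio by one-way ANOVA method of moments.

    Unbalanced design handled with the standard n0 coefficient.  A
    nonpositive between-person component is clamped to ``floor`` with a
    warning, yielding a very large (but finite) ratio.
    """
    vals = days[[id_col, value_col]].dropna()
    if log_scale:
        vals = vals.assign(**{value_col: np.log(vals[value_col])})
    sizes = vals.groupby(id_col, sort=False)[value_col].size()
    if (sizes >= 2).sum() < 2:
        raise DomainError("need >= 2 persons with >= 2 collection days")
    k = len(sizes)
    N = int(sizes.sum())
    grand = vals[value_col].mean()
    means = vals.groupby(id_col, sort=False)[value_col].mean()
    ssw = float(((vals[value_col] - vals[id_col].map(means)) ** 2).sum())
    ssb = float((sizes * (means - grand) ** 2).sum())
    msw = ssw / (N - k)
    msb = ssb / (k - 1)
    n0 = (N - float((sizes**2).sum()) / N) / (k - 1)
    sigma2_b = (msb - msw) / n0
    clamped = sigma2_b <= 0
    if clamped:
        warnings.warn("nonpositive between-person variance component; clamped",
                      stacklevel=2)
        sigma2_b = floor
    return LambdaEstimate(lambda_x=msw / sigma2_b, n_collections=N / k,
                          sigma2_within=msw, sigma2_between=sigma2_b, clamped=clamped)


def deattenuate(observed_cc: float, lambda_x: float, n: float) -> float:
    """Correct an observed correlation for day-to-day measurement error.

    Returns observed_cc * sqrt(1 + lambda_x/n); magnitudes above 1 are
    reported as computed, with a warning.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    if lambda_x < 0:
        raise DomainError("lambda_x must be >= 0")
    adjusted = observed_cc * np.sqrt(1.0 + lambda_x / n)
    if abs(adjusted) > 1.0:
        warnings.warn(f"deattenuated correlation {adjusted:.3f} outside [-1, 1]",
                      stacklevel=2)
    return float(adjusted)


@dataclass
class BlandAltman:
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    prop_bias_slope: float
    n: int


def bland_altman(estimates, measured) -> BlandAltman:
    """Agreement statistics: mean difference, 1.96-SD limits, bias slope.

    Differences are estimate minus measured; the proportional-bias slope
    regresses the difference on the pairwise mean (negative slope means
    overestimation at low and underestimation at high intake).
    """
    est = np.asarray(estimates, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if est.size != meas.size:
        raise DomainError("estimates and measured must have equal length")
    if est.size < 2:
        raise DomainError("need at least two pairs")
    d = est - meas
    m = (est + meas) / 2.0
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    if np.ptp(m) == 0:
        slope = 0.0
    else:
        slope = float(np.polyfit(m, d, 1)[0])
    return BlandAltman(mean_diff, sd_diff, mean_diff - 1.96 * sd_diff,
                       mean_diff + 1.96 * sd_diff, slope, int(est.size))


STRATA = {"all": None, "male": 1, "female": 2}

#: outcome key -> (measured column, daily column)
_OUTCOMES = {"sodium": ("na_mg_per_day", "na_mg"), "nak": ("nak_mol", "nak_mol")}


def _correlate(x, y, use_pearson: bool) -> float:
    if use_pearson:
        return float(stats.pearsonr(np.asarray(x, float), np.asarray(y, float)).statistic)
    return spearman_cc(x, y)


def compare_approaches(val_frame: pd.DataFrame, urine_days: pd.DataFrame,
                       equations: Mapping[str, Mapping[str, PredictionEquation]],
                       *, deattenuate_n: str = "mean", fixed_n: int = 5,
                       energy_method: str = "residual", use_pearson: bool = False,
                       min_stratum: int = 3) -> list[dict]:
    """Validation-group comparison of the empirical-weight equations with
    the food-composition estimator.

    ``val_frame`` holds one row per validation participant with measured
    means, coded items/characteristics and food-composition columns;
    ``urine_days`` the same participants' complete collection days with
    daily ``na_mg``/``nak_mol`` values.  ``equations`` maps outcome key
    (``sodium``/``nak``) to variant (``behavior_only``/
    ``with_characteristics``) to equation.  Returns one report row per
    outcome x stratum x variant plus a food-composition comparator.
    """
    if energy_method != "none":
        fci_na_adj = energy_adjust(val_frame["fci_na_mg"].to_numpy(),
                                   val_frame["energy_kcal"].to_numpy(), energy_method)
    else:
        fci_na_adj = val_frame["fci_na_mg"].to_numpy()
    fci_nak = questionnaire_nak_ratio(val_frame["fci_na_mg"].to_numpy(),
                                      val_frame["fci_k_mg"].to_numpy())
    comparator = {"sodium": fci_na_adj, "nak": fci_nak}

    rows: list[dict] = []
    for outcome, (meas_col, day_col) in _OUTCOMES.items():
        for stratum, sex_code in STRATA.items():
            mask = (np.ones(len(val_frame), dtype=bool) if sex_code is None
                    else (val_frame["sex"].to_numpy() == sex_code))
            sub = val_frame[mask]
            if len(sub) < min_stratum:
                warnings.warn(f"stratum '{stratum}' has n<{min_stratum}; skipped",
                              stacklevel=2)
                continue
            days_sub = urine_days[urine_days["participant_id"].isin(sub["participant_id"])]
            lam = estimate_lambda(days_sub, day_col)
            n_coll = lam.n_collections if deattenuate_n == "mean" else float(fixed_n)
            measured = sub[meas_col].to_numpy(dtype=float)
            comp = comparator[outcome][mask]
            comp_crude = _correlate(comp, measured, use_pearson)
            comp_adj = deattenuate(comp_crude, lam.lambda_x, n_coll)
            for variant, eq in equations[outcome].items():
                est = predict_frame(eq, sub)
                crude = _correlate(est, measured, use_pearson)
                ba = bland_altman(est, measured)
                rows.append({
                    "outcome": outcome, "stratum": stratum, "variant": variant,
                    "n": int(len(sub)),
                    "crude_cc": crude,
                    "adjusted_cc": deattenuate(crude, lam.lambda_x, n_coll),
                    "lambda_x": lam.lambda_x,
                    "n_collections_used": n_coll,
                    "estimated_mean": float(est.mean()),
                    "estimated_sd": float(est.std(ddof=1)),
                    "measured_mean": float(measured.mean()),
                    "measured_sd": float(measured.std(ddof=1)),
                    "ba_mean_diff": ba.mean_diff,
                    "ba_loa": [ba.loa_lower, ba.loa_upper],
                    "ba_prop_bias_slope": ba.prop_bias_slope,
                    "comparator_crude_cc": comp_crude,
                    "comparator_adjusted_cc": comp_adj,
                })
    return rows


def plot_bland_altman(estimates, measured, path, title: str = "") -> None:
    """Difference-vs-mean agreement plot written to ``path`` (SVG/PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = bland_altman(estimates, measured)
    est = np.asarray(estimates, float)
    meas = np.asarray(measured, float)
    m, d = (est + meas) / 2, est - meas
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(m, d, s=12, alpha=0.7)
    for yv, style in ((ba.mean_diff, "-"), (ba.loa_lower, "--"), (ba.loa_upper, "--")):
        ax.axhline(yv, color="crimson", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of estimate and measured")
    ax.set_ylabel("estimate - measured")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
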