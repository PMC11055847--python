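"""24-h urine processing.

A portable collection device retains a 1/50 aliquot of each void, so the
recorded aliquot volume times 50 is the day's total urine volume.  Daily
excretion is reconstructed from the measured electrolyte concentration and
that volume:

    Na (mg/day) = [Na] (mEq/L) x aliquot (mL) x 50/1000 x 23
    K  (mg/day) = [K]  (mEq/L) x aliquot (mL) x 50/1000 x 39

and the daily sodium-to-potassium molar ratio is simply [Na]/[K] because
the volume cancels.

Completeness rules: a day with two or more missed voids is incomplete; a
person with three or more incomplete days is excluded; a day with exactly
one missed void is corrected by substituting the person's mean over fully
collected days.  A total volume of 10 L/day or more is flagged as
implausible but does not exclude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, UndefinedRatioError

NA_MG_PER_MEQ = 23.0  # molar mass of sodium, mg per mEq
K_MG_PER_MEQ = 39.0  # molar mass of potassium, mg per mEq
ALIQUOT_FACTOR = 50.0  # device keeps a 1/50 portion
MAX_PLAUSIBLE_VOLUME_ML = 10_000.0  # complete-volume plausibility bound


@dataclass
class UrineCollectionDay:
    """One day's raw urine measurements for one person."""

    participant_id: str
    day_index: int
    na_conc: float  # mEq/L
    k_conc: float  # mEq/L
    aliquot_volume_ml: float  # obtained amount in the 1/50 device
    missed_voids: int = 0


@dataclass
class ExcretionSummary:
    """Per-person mean 24-h excretion after completeness rules."""

    participant_id: str
    n_complete_days: int
    na_mg_per_day: float
    k_mg_per_day: float
    nak_mol: float
    included: bool
    exclusion_reason: str | None = None
    volume_flag: bool = False


def _check_nonnegative(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise DomainError(f"{name} must be nonnegative")
    return arr


def compute_na_excretion(na_conc, aliquot_volume_ml):
    """24-h urinary sodium excretion in mg/day.

    Parameters are the measured sodium concentration (mEq/L) and the
    obtained aliquot volume (mL); both may be array-like.
    """
    c = _check_nonnegative("na_conc", na_conc)
    v = _check_nonnegative("aliquot_volume_ml", aliquot_volume_ml)
    out = c * v * ALIQUOT_FACTOR / 1000.0 * NA_MG_PER_MEQ
    return float(out) if out.ndim == 0 else out


def compute_k_excretion(k_conc, aliquot_volume_ml):
    """24-h urinary potassium excretion in mg/day."""
    c = _check_nonnegative("k_conc", k_conc)
    v = _check_nonnegative("aliquot_volume_ml", aliquot_volume_ml)
    out = c * v * ALIQUOT_FACTOR / 1000.0 * K_MG_PER_MEQ
    return float(out) if out.ndim == 0 else out


def compute_urine_nak(na_conc, k_conc):
    """Daily sodium-to-potassium molar ratio from concentrations."""
    c_na = _check_nonnegative("na_conc", na_conc)
    c_k = np.asarray(k_conc, dtype=float)
    if np.any(c_k <= 0):
        raise UndefinedRatioError("k_conc must be strictly positive for the Na/K ratio")
    out = c_na / c_k
    return float(out) if out.ndim == 0 else out


def apply_completeness_rules(days: Sequence[UrineCollectionDay]) -> ExcretionSummary:
    """Summarize one person's collection days into mean 24-h values.

    Days with ``missed_voids >= 2`` are incomplete.  Three or more
    incomplete days exclude the person.  A single-miss day is replaced by
    the person's complete-day mean before averaging.
    """
    if not days:
        raise DomainError("at least one collection day is required")
    pid = days[0].participant_id
    incomplete = [d for d in days if d.missed_voids >= 2]
    complete = [d for d in days if d.missed_voids == 0]
    single_miss = [d for d in days if d.missed_voids == 1]

    volume_flag = any(
        d.aliquot_volume_ml * ALIQUOT_FACTOR >= MAX_PLAUSIBLE_VOLUME_ML for d in days
    )
    if volume_flag:
        warnings.warn(
            f"participant {pid}: total volume >= {MAX_PLAUSIBLE_VOLUME_ML/1000:.0f} L on "
            "at least one day; flagged but not excluded",
            stacklevel=2,
        )

    if len(incomplete) >= 3:
        return ExcretionSummary(pid, len(complete), np.nan, np.nan, np.nan, False,
                                exclusion_reason="incomplete_days>=3", volume_flag=volume_flag)
    if not complete:
        # cannot form the complete-day mean needed for correction
        return ExcretionSummary(pid, 0, np.nan, np.nan, np.nan, False,
                                exclusion_reason="no_complete_days", volume_flag=volume_flag)

    na_c = [compute_na_excretion(d.na_conc, d.aliquot_volume_ml) for d in complete]
    k_c = [compute_k_excretion(d.k_conc, d.aliquot_volume_ml) for d in complete]
    r_c = [compute_urine_nak(d.na_conc, d.k_conc) for d in complete]
    na_mean_c, k_mean_c, r_mean_c = (float(np.mean(v)) for v in (na_c, k_c, r_c))

    # single-miss days contribute the complete-day mean for every quantity
    n_used = len(complete) + len(single_miss)
    na = (sum(na_c) + len(single_miss) * na_mean_c) / n_used
    k = (sum(k_c) + len(single_miss) * k_mean_c) / n_used
    r = (sum(r_c) + len(single_miss) * r_mean_c) / n_used
    return ExcretionSummary(pid, len(complete), na, k, r, True, volume_flag=volume_flag)


def daily_values(days: pd.DataFrame) -> pd.DataFrame:
    """Attach computed daily excretion columns to a urine-day table.

    Expects columns ``na_conc``, ``k_conc``, ``aliquot_volume_ml``; adds
    ``na_mg``, ``k_mg`` and ``nak_mol``.
    """
    out = days.copy()
    out["na_mg"] = compute_na_excretion(out["na_conc"].to_numpy(),
                                        out["aliquot_volume_ml"].to_numpy())
    out["k_mg"] = compute_k_excretion(out["k_conc"].to_numpy(),
                                      out["aliquot_volume_ml"].to_numpy())
    out["nak_mol"] = compute_urine_nak(out["na_conc"].to_numpy(), out["k_conc"].to_numpy())
    return out


def summarize_excretion(days: pd.DataFrame) -> tuple[pd.DataFrame, list[dict]]:
    """Vectorized per-person summary of a urine-day table.

    Returns the summary frame (one row per participant, in first-appearance
    order) and an exclusion log.  Because single-miss days are replaced by
    the complete-day mean, summary means equal complete-day means; the rule
    is kept explicit in :func:`apply_completeness_rules` and both paths are
    cross-checked in the test-suite.
    """
    req = {"participant_id", "na_conc", "k_conc", "aliquot_volume_ml", "missed_voids"}
    missing = req - set(days.columns)
    if missing:
        raise DomainError(f"urine-day table is missing columns: {sorted(missing)}")
    dv = daily_values(days)
    dv["_incomplete"] = (dv["missed_voids"] >= 2).astype(int)
    dv["_complete"] = (dv["missed_voids"] == 0).astype(int)
    grp = dv.groupby("participant_id", sort=False)
    n_incomplete = grp["_incomplete"].sum()
    n_complete = grp["_complete"].sum()
    comp = dv[dv["_complete"] == 1].groupby("participant_id", sort=False)[
        ["na_mg", "k_mg", "nak_mol"]
    ].mean()

    total_volume = dv["aliquot_volume_ml"] * ALIQUOT_FACTOR
    vol_flag = (total_volume >= MAX_PLAUSIBLE_VOLUME_ML).groupby(dv["participant_id"]).any()

    rows, log = [], []
    for pid in dv["participant_id"].drop_duplicates():
        ni, nc = int(n_incomplete[pid]), int(n_complete[pid])
        if ni >= 3:
            reason = "incomplete_days>=3"
        elif nc == 0:
            reason = "no_complete_days"
        else:
            reason = None
        included = reason is None
        if not included:
            log.append({"participant_id": pid, "reason": reason,
                        "n_incomplete": ni, "n_complete": nc})
        mean = comp.loc[pid] if (included and pid in comp.index) else None
        rows.append({
            "participant_id": pid,
            "n_complete_days": nc,
            "na_mg_per_day": float(mean["na_mg"]) if included else np.nan,
            "k_mg_per_day": float(mean["k_mg"]) if included else np.nan,
            "nak_mol": float(mean["nak_mol"]) if included else np.nan,
            "included": included,
            "exclusion_reason": reason,
            "volume_flag": bool(vol_flag.get(pid, False)),
        })
    return pd.DataFrame(rows), log
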