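"""Synthetic cohort generator with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* latent habitual 24-h sodium excretion and Na/K molar ratio are exact
  linear scores of each person's true ordinal behavior codes (and,
  optionally, characteristics) under configured true weights — so the
  modeling stage can be checked as a parameter-recovery problem;
* day-to-day variation is multiplicative lognormal, with the
  within-person log-variance set to ``lambda_x`` times the between-person
  variance of the log latent score; the noise is mean-one so day values
  are unbiased for the latent mean;
* 3-5 collection days per person, with occasional single missed voids on
  otherwise complete days and whole incomplete days (two missed voids)
  generated completely at random;
* two FFQ administrations whose ordinal codes are independent +-1
  perturbations of the truth, plus a food-composition estimator with its
  own multiplicative error;
* ordinal behavior items share a latent "salt liking" factor, so items
  correlate with each other (and hence each item's marginal trend is
  stronger than its partial weight), as observed in real cohorts.

Latent potassium excretion is derived from the sodium and ratio scores:
K (mg) = 39 * (Na mg / 23) / ratio.  The food-composition potassium
estimate is scaled by 1.3 to the intake scale, matching the questionnaire
ratio formula's excretion conversion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .config import CohortConfig
from .errors import ConfigError
from .ffq import FFQRecord, K_INTAKE_TO_EXCRETION, assign_quartiles, default_coding_map
from .urine import ALIQUOT_FACTOR, K_MG_PER_MEQ, NA_MG_PER_MEQ

#: Marginal category counts of the ordinal behavior items, used as
#: categorical sampling weights (a 244-person field survey's spread).
BEHAVIOR_MARGINALS: dict[str, tuple[int, ...]] = {
    "taste_preference": (17, 99, 120, 8, 0),
    "soy_sauce": (56, 73, 85, 25, 5),
    "noodle_soup": (67, 71, 46, 34, 26),
    "spices": (79, 68, 53, 44),
    "wasabi": (53, 92, 80, 19),
    "processed_meat": (55, 81, 70, 38),
    "salted_fish": (52, 76, 65, 51),
    "pickled_vegetables": (46, 39, 65, 94),
    "instant_food": (75, 108, 53, 8),
    "eating_out": (66, 99, 58, 21),
    "noodles": (55, 97, 70, 22),
    "miso_soup_bowls": (75, 82, 69, 18),
}

BEHAVIOR_ITEMS = tuple(BEHAVIOR_MARGINALS)

#: Seventeen food groups entering the stepwise screen; median g/day of a
#: lognormal intake distribution (log-scale SD 0.55).
FOOD_GROUP_MEDIANS: dict[str, float] = {
    "cereals": 420.0, "potatoes": 55.0, "sugars": 10.0, "pulses": 60.0,
    "vegetables": 270.0, "fruits": 170.0, "mushrooms": 15.0, "seaweeds": 12.0,
    "fishes": 90.0, "meats": 70.0, "eggs": 35.0, "milk_products": 180.0,
    "oils": 12.0, "confectioneries": 40.0, "beverages": 600.0,
    "seasonings": 35.0, "soybean_products": 50.0,
}
FOOD_GROUPS = tuple(FOOD_GROUP_MEDIANS)
FOOD_GROUP_LOG_SD = 0.55
#: groups whose intake correlates negatively with the salt-liking factor
POTASSIUM_GROUPS = ("vegetables", "fruits", "milk_products")

CHARACTERISTICS = ("sex", "age", "bmi", "htn_med", "smoker", "alcohol")


@dataclass
class ParticipantTruth:
    """Ground truth for one synthetic participant."""

    participant_id: str
    sex: int  # 1 male, 2 female
    age: float
    bmi: float
    htn_med: int
    alcohol: int  # 1 none .. 4 daily
    smoker: int
    latent_na_mg: float
    latent_k_mg: float
    latent_nak: float
    true_codes: dict = field(default_factory=dict)
    true_quartiles: dict = field(default_factory=dict)
    true_group_intakes: dict = field(default_factory=dict)


@dataclass
class SimulatedCohort:
    """Bundle of generated tables plus the generating truth."""

    participants: pd.DataFrame
    urine_days: pd.DataFrame
    ffq: pd.DataFrame
    truth: dict


def linear_score(intercept: float, weights: Mapping[str, float], frame: pd.DataFrame,
                 *, weights_field: str = "true_weights") -> np.ndarray:
    """Deterministic linear score: intercept + sum(weight * column)."""
    score = np.full(len(frame), float(intercept))
    for var, w in weights.items():
        if var not in frame.columns:
            raise ConfigError(weights_field, f"unknown score variable '{var}'")
        score = score + float(w) * frame[var].to_numpy(dtype=float)
    return score


def _ordinal_sample(rng: np.random.Generator, z: np.ndarray, counts, loading: float) -> np.ndarray:
    """Ordered-probit draw with marginals from `counts`, correlated with z."""
    p = np.asarray(counts, dtype=float)
    p = p / p.sum()
    cum = np.cumsum(p)[:-1]
    with np.errstate(divide="ignore"):
        tau = stats.norm.ppf(np.clip(cum, 0.0, 1.0))
    u = loading * z + np.sqrt(1.0 - loading**2) * rng.standard_normal(z.size)
    return 1 + (u[:, None] > tau[None, :]).sum(axis=1)


def generate_participants_frame(config: CohortConfig,
                                rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Participant truth table: characteristics, true codes, latent scores."""
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_participants

    df = pd.DataFrame({
        "participant_id": [f"P{i+1:04d}" for i in range(n)],
        "sex": rng.choice([1, 2], size=n, p=[0.44, 0.56]),
        "age": np.clip(np.round(rng.normal(56.0, 9.0, n), 1), 35.0, 80.0),
        "bmi": np.clip(np.round(rng.normal(23.2, 2.9, n), 1), 16.0, 35.0),
        "smoker": (rng.random(n) < 0.12).astype(int),
        "alcohol": rng.choice([1, 2, 3, 4], size=n, p=[0.32, 0.20, 0.17, 0.31]),
        "htn_med": (rng.random(n) < 0.055).astype(int),
    })

    z = rng.standard_normal(n)  # shared salt-liking factor
    for item, counts in BEHAVIOR_MARGINALS.items():
        df[item] = _ordinal_sample(rng, z, counts, config.behavior_corr)

    # food-group intakes: lognormal, potassium sources anti-correlated with z
    for group in FOOD_GROUPS:
        load = -0.6 * config.behavior_corr if group in POTASSIUM_GROUPS else 0.0
        eps = load * z + np.sqrt(1.0 - load**2) * rng.standard_normal(n)
        df[f"{group}_g"] = np.exp(np.log(FOOD_GROUP_MEDIANS[group]) + FOOD_GROUP_LOG_SD * eps)
    if n >= 4:
        for group in FOOD_GROUPS:
            df[f"{group}_q"] = assign_quartiles(df[f"{group}_g"].to_numpy())
    else:  # degenerate cohorts cannot be quartiled; quartile weights then invalid
        for group in FOOD_GROUPS:
            df[f"{group}_q"] = 1

    df["latent_na_mg"] = linear_score(config.intercept_na, config.true_weights_na, df,
                                      weights_field="true_weights_na")
    df["latent_nak"] = linear_score(config.intercept_nak, config.true_weights_nak, df,
                                    weights_field="true_weights_nak")
    if np.any(df["latent_na_mg"] <= 0):
        raise ConfigError("true_weights_na", "weights produce nonpositive latent excretion")
    if np.any(df["latent_nak"] <= 0):
        raise ConfigError("true_weights_nak", "weights produce nonpositive latent ratio")
    df["latent_k_mg"] = (K_MG_PER_MEQ * (df["latent_na_mg"] / NA_MG_PER_MEQ)
                         / df["latent_nak"])
    return df


def generate_participants(config: CohortConfig) -> list[ParticipantTruth]:
    """Ground-truth participants as typed records (wraps the frame API)."""
    df = generate_participants_frame(config)
    out = []
    for _, row in df.iterrows():
        out.append(ParticipantTruth(
            participant_id=row["participant_id"],
            sex=int(row["sex"]), age=float(row["age"]), bmi=float(row["bmi"]),
            htn_med=int(row["htn_med"]), alcohol=int(row["alcohol"]),
            smoker=int(row["smoker"]),
            latent_na_mg=float(row["latent_na_mg"]),
            latent_k_mg=float(row["latent_k_mg"]),
            latent_nak=float(row["latent_nak"]),
            true_codes={item: int(row[item]) for item in BEHAVIOR_ITEMS},
            true_quartiles={g: int(row[f"{g}_q"]) for g in FOOD_GROUPS},
            true_group_intakes={g: float(row[f"{g}_g"]) for g in FOOD_GROUPS},
        ))
    return out


def _within_log_sd(latent: np.ndarray, lambda_x: float) -> float:
    sigma_b2 = float(np.var(np.log(latent)))
    return float(np.sqrt(lambda_x * sigma_b2))


def generate_urine_days_frame(participants: pd.DataFrame, config: CohortConfig,
                              rng: np.random.Generator) -> pd.DataFrame:
    """Daily urine measurements consistent with the excretion formulas.

    Each day's true excretion is the latent mean times mean-one lognormal
    noise; the day is then expressed as (concentration, aliquot volume) so
    that the excretion formulas recover it exactly on complete days.
    Incomplete days (2 missed voids) and single-miss days capture only a
    fraction of the volume.
    """
    n, d = len(participants), config.n_collection_days
    latent_na = participants["latent_na_mg"].to_numpy()
    latent_k = participants["latent_k_mg"].to_numpy()
    sw_na = _within_log_sd(latent_na, config.lambda_x)
    sw_k = _within_log_sd(latent_k, config.lambda_x)

    def day_noise(sw: float) -> np.ndarray:
        if sw == 0.0:
            return np.ones((n, d))
        return np.exp(rng.normal(-sw**2 / 2.0, sw, size=(n, d)))

    na_day = latent_na[:, None] * day_noise(sw_na)
    k_day = latent_k[:, None] * day_noise(sw_k)

    probs = config.completeness_probs_normalized
    complete_count = rng.choice([d, d - 1, d - 2], size=n, p=probs)
    # a small share of persons fail on >= 3 days and will be excluded downstream
    dropout = rng.random(n) < config.dropout_prob
    complete_count = np.where(dropout, d - 3, complete_count)
    day_rank = rng.random((n, d)).argsort(axis=1)  # random day ordering per person
    incomplete = day_rank < (d - complete_count)[:, None]
    single_miss = (~incomplete) & (rng.random((n, d)) < config.single_miss_prob)
    missed = np.where(incomplete, 2, np.where(single_miss, 1, 0))

    frac = np.ones((n, d))
    frac[incomplete] = rng.uniform(0.4, 0.8, int(incomplete.sum()))
    frac[single_miss] = rng.uniform(0.75, 0.95, int(single_miss.sum()))

    total_volume = np.clip(rng.normal(1700.0, 450.0, size=(n, d)), 600.0, 4000.0)
    na_conc = na_day / NA_MG_PER_MEQ / (total_volume / 1000.0)
    k_conc = k_day / K_MG_PER_MEQ / (total_volume / 1000.0)
    aliquot = total_volume * frac / ALIQUOT_FACTOR

    pid = np.repeat(participants["participant_id"].to_numpy(), d)
    return pd.DataFrame({
        "participant_id": pid,
        "day_index": np.tile(np.arange(1, d + 1), n),
        "na_conc": na_conc.ravel(),
        "k_conc": k_conc.ravel(),
        "aliquot_volume_ml": aliquot.ravel(),
        "missed_voids": missed.ravel(),
        "true_na_mg": na_day.ravel(),
        "true_k_mg": k_day.ravel(),
        "true_nak": ((na_day / NA_MG_PER_MEQ) / (k_day / K_MG_PER_MEQ)).ravel(),
    })


def generate_urine_days(truth: ParticipantTruth, config: CohortConfig,
                        rng: np.random.Generator | None = None):
    """Per-person convenience wrapper returning UrineCollectionDay records.

    Within-person noise needs a cohort-level between-person variance; a
    single person has none, so the day noise here uses the configured
    lambda_x against the default cohort's log-scale spread (0.12 SD).
    """
    from .urine import UrineCollectionDay

    rng = np.random.default_rng(config.seed) if rng is None else rng
    frame = pd.DataFrame({
        "participant_id": [truth.participant_id],
        "latent_na_mg": [truth.latent_na_mg],
        "latent_k_mg": [truth.latent_k_mg],
    })
    # emulate a cohort-level spread for the single-person case
    sw = float(np.sqrt(config.lambda_x)) * 0.12
    d = config.n_collection_days
    noise_na = np.exp(rng.normal(-sw**2 / 2, sw, d)) if sw else np.ones(d)
    noise_k = np.exp(rng.normal(-sw**2 / 2, sw, d)) if sw else np.ones(d)
    probs = config.completeness_probs_normalized
    complete_count = int(rng.choice([d, d - 1, d - 2], p=probs))
    order = rng.permutation(d)
    days = []
    for j in range(d):
        na_day = truth.latent_na_mg * noise_na[j]
        k_day = truth.latent_k_mg * noise_k[j]
        if order[j] < d - complete_count:
            missed, frac = 2, float(rng.uniform(0.4, 0.8))
        elif rng.random() < config.single_miss_prob:
            missed, frac = 1, float(rng.uniform(0.75, 0.95))
        else:
            missed, frac = 0, 1.0
        vol = float(np.clip(rng.normal(1700.0, 450.0), 600.0, 4000.0))
        days.append(UrineCollectionDay(
            participant_id=truth.participant_id, day_index=j + 1,
            na_conc=na_day / NA_MG_PER_MEQ / (vol / 1000.0),
            k_conc=k_day / K_MG_PER_MEQ / (vol / 1000.0),
            aliquot_volume_ml=vol * frac / ALIQUOT_FACTOR,
            missed_voids=missed,
        ))
    return days


def _perturb_codes(codes: np.ndarray, n_levels: int, noise: float,
                   rng: np.random.Generator) -> np.ndarray:
    flip = rng.random(codes.size) < noise
    step = rng.integers(0, 2, codes.size) * 2 - 1
    return np.clip(codes + flip * step, 1, n_levels)


def generate_ffq_frame(participants: pd.DataFrame, config: CohortConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Two questionnaire administrations per person (long format).

    Ordinal codes are independent perturbations of the truth per
    instrument; reported food-group intakes carry multiplicative error and
    are re-quartiled cohort-wide per instrument; the food-composition
    estimates are the latent values times lognormal error (potassium on
    the intake scale, i.e. times 1.3).
    """
    cm = default_coding_map()
    n = len(participants)
    frames = []
    for instrument in ("FFQ1", "FFQ2"):
        df = pd.DataFrame({
            "participant_id": participants["participant_id"].to_numpy(),
            "instrument": instrument,
        })
        for item in BEHAVIOR_ITEMS:
            df[item] = _perturb_codes(participants[item].to_numpy(), cm.n_levels(item),
                                      config.ffq_item_noise, rng)
        for group in FOOD_GROUPS:
            true_g = participants[f"{group}_g"].to_numpy()
            noise = (np.exp(rng.normal(0.0, config.group_intake_noise_sd, n))
                     if config.group_intake_noise_sd else np.ones(n))
            df[f"{group}_g"] = true_g * noise
        if n >= 4:
            for group in FOOD_GROUPS:
                df[f"{group}_q"] = assign_quartiles(df[f"{group}_g"].to_numpy())
        else:
            for group in FOOD_GROUPS:
                df[f"{group}_q"] = 1

        def fci_noise() -> np.ndarray:
            if config.fci_error_sd == 0.0:
                return np.ones(n)
            return np.exp(rng.normal(0.0, config.fci_error_sd, n))

        df["fci_na_mg"] = participants["latent_na_mg"].to_numpy() * fci_noise()
        df["fci_k_mg"] = (participants["latent_k_mg"].to_numpy()
                          * K_INTAKE_TO_EXCRETION * fci_noise())
        energy = (2600.0 - 400.0 * (participants["sex"].to_numpy() - 1)
                  + 30.0 * (participants["bmi"].to_numpy() - 23.0)
                  + rng.normal(0.0, 250.0, n))
        df["energy_kcal"] = np.clip(energy, 800.0, None)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def generate_ffq_pair(truth: ParticipantTruth, config: CohortConfig,
                      rng: np.random.Generator | None = None) -> tuple[FFQRecord, FFQRecord]:
    """Per-person FFQ pair (FFQ1, FFQ2) as typed records.

    Quartile codes are the person's true cohort quartiles perturbed with
    the same item noise (a single person cannot be re-quartiled); the
    cohort-level :func:`generate_ffq_frame` recomputes them properly.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    cm = default_coding_map()
    records = []
    for instrument in ("FFQ1", "FFQ2"):
        codes = {
            item: int(_perturb_codes(np.array([truth.true_codes[item]]), cm.n_levels(item),
                                     config.ffq_item_noise, rng)[0])
            for item in BEHAVIOR_ITEMS
        }
        quartiles = {
            g: int(_perturb_codes(np.array([truth.true_quartiles[g]]), 4,
                                  config.ffq_item_noise, rng)[0])
            for g in POTASSIUM_GROUPS
        }
        def noise(sd: float) -> float:
            return float(np.exp(rng.normal(0.0, sd))) if sd else 1.0
        records.append(FFQRecord(
            participant_id=truth.participant_id, instrument=instrument,
            behavior_codes=codes, group_quartiles=quartiles,
            fci_na_mg=truth.latent_na_mg * noise(config.fci_error_sd),
            fci_k_mg=truth.latent_k_mg * K_INTAKE_TO_EXCRETION * noise(config.fci_error_sd),
            energy_kcal=float(np.clip(
                2600.0 - 400.0 * (truth.sex - 1) + 30.0 * (truth.bmi - 23.0)
                + rng.normal(0.0, 250.0), 800.0, None)),
        ))
    return records[0], records[1]


def generate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Full cohort: participants, urine days and FFQ tables, plus truth."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_part, rng_urine, rng_ffq = (np.random.default_rng(s) for s in ss.spawn(3))
    participants = generate_participants_frame(config, rng_part)
    urine_days = generate_urine_days_frame(participants, config, rng_urine)
    ffq = generate_ffq_frame(participants, config, rng_ffq)
    truth = {
        "seed": config.seed,
        "n_participants": config.n_participants,
        "intercept_na": config.intercept_na,
        "true_weights_na": dict(config.true_weights_na),
        "intercept_nak": config.intercept_nak,
        "true_weights_nak": dict(config.true_weights_nak),
        "lambda_x": config.lambda_x,
        "ffq_item_noise": config.ffq_item_noise,
        "fci_error_sd": config.fci_error_sd,
        "within_log_sd_na": _within_log_sd(participants["latent_na_mg"].to_numpy(),
                                           config.lambda_x),
        "between_log_var_na": float(np.var(np.log(participants["latent_na_mg"]))),
    }
    return SimulatedCohort(participants, urine_days, ffq, truth)


def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, str]:
    """Write participants.csv, urine_days.csv, ffq.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (("participants", cohort.participants),
                        ("urine_days", cohort.urine_days),
                        ("ffq", cohort.ffq)):
        p = outdir / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = str(p)
    p = outdir / "truth.json"
    with open(p, "w") as fh:
        json.dump(cohort.truth, fh, indent=2)
    paths["truth"] = str(p)
    return paths
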