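"""Food-frequency questionnaire encoding and food-composition arithmetic.

Behavior items are coded as ordinal integers (1..4 or 1..5) following a
versioned coding map shipped with the package (``data/coding_map.yaml``);
users can supply their own map to re-declare category boundaries.  Food
groups are summarized as cohort-wide quartile codes.  The questionnaire
Na/K molar ratio divides estimated potassium intake by 1.3 before the
molar conversion because only about 77% of dietary potassium is excreted
in urine, which makes the questionnaire ratio commensurate with the
urinary one.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import CodingError, DegenerateDataError, DomainError, UndefinedRatioError

#: conversion of potassium intake to its urinary-excretion equivalent
K_INTAKE_TO_EXCRETION = 1.3
NA_MG_PER_MMOL = 23.0
K_MG_PER_MMOL = 39.0


@dataclass
class CodingMap:
    """Item -> ordinal-category definitions (labels or frequency bounds)."""

    version: int
    items: dict
    quartile_groups: list[str]

    @classmethod
    def default(cls) -> "CodingMap":
        text = (
            importlib.resources.files("saltscore").joinpath("data/coding_map.yaml").read_text()
        )
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_dict(cls, raw: Mapping) -> "CodingMap":
        return cls(
            version=int(raw["version"]),
            items={k: dict(v) for k, v in raw["items"].items()},
            quartile_groups=list(raw.get("quartile_groups", [])),
        )

    @classmethod
    def from_yaml(cls, path) -> "CodingMap":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def n_levels(self, item: str) -> int:
        spec = self._spec(item)
        if spec["kind"] == "labels":
            return len(spec["labels"])
        return len(spec["upper_bounds"]) + 1

    def _spec(self, item: str) -> dict:
        try:
            return self.items[item]
        except KeyError:
            raise CodingError(item, None, "unknown item") from None

    def code(self, item: str, raw) -> int:
        """Map a raw response (label or frequency) to its ordinal code."""
        spec = self._spec(item)
        if isinstance(raw, str):
            if spec["kind"] != "labels":
                raise CodingError(item, raw, "item takes a numeric frequency, not a label")
            labels = [lab.lower() for lab in spec["labels"]]
            try:
                return labels.index(raw.strip().lower()) + 1
            except ValueError:
                raise CodingError(item, raw) from None
        value = float(raw)
        if value < 0:
            raise CodingError(item, raw, "negative frequency")
        if spec["kind"] == "labels":
            # allow a pre-coded ordinal to pass through
            code = int(value)
            if code != value or not 1 <= code <= len(spec["labels"]):
                raise CodingError(item, raw, "out-of-range ordinal code")
            return code
        bounds = np.asarray(spec["upper_bounds"], dtype=float)
        # closed on the left, open on the right: value == bound -> next category
        return int(np.searchsorted(bounds, value, side="right")) + 1


_DEFAULT_MAP: CodingMap | None = None


def default_coding_map() -> CodingMap:
    global _DEFAULT_MAP
    if _DEFAULT_MAP is None:
        _DEFAULT_MAP = CodingMap.default()
    return _DEFAULT_MAP


def code_behavior_item(item: str, raw, coding_map: CodingMap | None = None) -> int:
    """Ordinal code of one behavior item from a label or frequency."""
    cm = coding_map or default_coding_map()
    return cm.code(item, raw)


def aggregate_food_group_frequency(item_frequencies: Sequence[float]) -> float:
    """Weekly frequency of a food group: sum of its member items."""
    freqs = np.asarray(list(item_frequencies), dtype=float)
    if freqs.size and np.any(freqs < 0):
        raise DomainError("frequencies must be nonnegative")
    return float(freqs.sum())


def assign_quartiles(values) -> np.ndarray:
    """Cohort-wide quartile codes 1..4, balanced to n/4 +- 1 per quartile.

    Ties are broken by stable input (participant) order.  A degenerate
    all-equal input yields all-1 codes with a warning.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 4:
        raise DomainError("quartile assignment needs at least four persons")
    if np.ptp(arr) == 0:
        warnings.warn("degenerate distribution: all values equal; assigning quartile 1",
                      stacklevel=2)
        return np.ones(arr.size, dtype=int)
    order = np.argsort(arr, kind="stable")
    ranks = np.empty(arr.size, dtype=int)
    ranks[order] = np.arange(arr.size)
    return (ranks * 4) // arr.size + 1


def questionnaire_nak_ratio(na_mg, k_mg):
    """Na/K molar ratio from questionnaire intake estimates.

    (na_mg / 23) / ((k_mg / 1.3) / 39); the 1.3 divisor converts potassium
    intake to its expected urinary excretion.
    """
    na = np.asarray(na_mg, dtype=float)
    k = np.asarray(k_mg, dtype=float)
    if np.any(na < 0):
        raise DomainError("na_mg must be nonnegative")
    if np.any(k <= 0):
        raise UndefinedRatioError("k_mg must be strictly positive")
    out = (na / NA_MG_PER_MMOL) / ((k / K_INTAKE_TO_EXCRETION) / K_MG_PER_MMOL)
    return float(out) if out.ndim == 0 else out


def energy_adjust(values, energy_kcal, method: str = "residual"):
    """Energy-adjust a nutrient across the cohort.

    ``residual`` regresses the nutrient on energy and returns residual plus
    cohort mean (mean-preserving); ``density`` scales by mean energy over
    personal energy; ``none`` returns the input.  Never applied to the
    Na/K ratio, which is already intake-scale free.
    """
    vals = np.asarray(values, dtype=float)
    energy = np.asarray(energy_kcal, dtype=float)
    if vals.shape != energy.shape:
        raise DomainError("values and energy must have the same length")
    if np.any(energy <= 0):
        raise DomainError("energy must be strictly positive")
    if method == "none":
        return vals.copy()
    if method == "density":
        return vals / energy * energy.mean()
    if method != "residual":
        raise DomainError(f"unknown energy-adjustment method: {method}")
    if np.ptp(energy) == 0:
        warnings.warn("zero energy variance; returning values unchanged", stacklevel=2)
        return vals.copy()
    X = np.column_stack([np.ones_like(energy), energy])
    beta, *_ = np.linalg.lstsq(X, vals, rcond=None)
    resid = vals - X @ beta
    return resid + vals.mean()


@dataclass
class FFQRecord:
    """One questionnaire administration for one person."""

    participant_id: str
    instrument: str  # FFQ1 | FFQ2
    behavior_codes: dict = field(default_factory=dict)
    group_quartiles: dict = field(default_factory=dict)
    fci_na_mg: float = np.nan
    fci_k_mg: float = np.nan
    energy_kcal: float = np.nan
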