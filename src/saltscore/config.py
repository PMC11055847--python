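"""Configuration objects for the synthetic cohort and the analysis pipeline.

All randomness in the package flows from the named seeds held here; no
function touches NumPy's global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

from .errors import ConfigError

#: Default true weights (mg/day per ordinal step) used by the synthetic
#: cohort: the behavior-only sodium equation fitted on the full sample.
DEFAULT_WEIGHTS_NA: dict[str, float] = {
    "taste_preference": 47.0,
    "soy_sauce": 187.0,
    "noodle_soup": 199.0,
    "pickled_vegetables": 101.0,
    "miso_soup_bowls": 161.0,
}
DEFAULT_INTERCEPT_NA = 2523.0

#: Default true weights (mol ratio per step) for the Na/K-ratio equation.
DEFAULT_WEIGHTS_NAK: dict[str, float] = {
    "taste_preference": 0.18,
    "soy_sauce": 0.32,
    "vegetables_q": -0.18,
    "fruits_q": -0.18,
    "milk_products_q": -0.13,
}
DEFAULT_INTERCEPT_NAK = 2.89

#: Share of subjects providing 5, 4 and 3 complete 24-h collections.  The
#: published shares (86/11/2%) sum to 99% through rounding; they are
#: renormalized at validation time.
DEFAULT_COMPLETENESS_PROBS = (0.86, 0.11, 0.02)


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    The defaults emulate the study conditions the analysis assumes: 244
    participants, five 24-h urine collections bracketed by two FFQ
    administrations, day-to-day within-person variance twice the
    between-person variance, and a food-composition estimator with a large
    multiplicative error.
    """

    n_participants: int = 244
    n_collection_days: int = 5
    #: probabilities that a person completes n, n-1, n-2 collection days
    collection_completeness_probs: tuple[float, float, float] = DEFAULT_COMPLETENESS_PROBS
    true_weights_na: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS_NA))
    intercept_na: float = DEFAULT_INTERCEPT_NA
    true_weights_nak: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS_NAK))
    intercept_nak: float = DEFAULT_INTERCEPT_NAK
    #: ratio of within- to between-person variance of daily log excretion
    lambda_x: float = 2.0
    #: probability that one FFQ ordinal code differs from truth by +-1
    ffq_item_noise: float = 0.2
    #: SD of the multiplicative (lognormal) error of FFQ food-group intakes
    group_intake_noise_sd: float = 0.25
    #: SD of the multiplicative error of the food-composition estimator
    fci_error_sd: float = 0.45
    #: probability that an otherwise complete day has a single missed void
    single_miss_prob: float = 0.05
    #: probability a person fails collection on >= 3 days (study: 5 of 253)
    dropout_prob: float = 5 / 253
    #: loading of the shared salt-liking factor on the ordinal behavior items
    behavior_corr: float = 0.35
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants", "must be >= 1")
        if self.n_collection_days < 3:
            raise ConfigError("n_collection_days", "must be >= 3")
        probs = tuple(self.collection_completeness_probs)
        if len(probs) != 3 or any(p < 0 for p in probs):
            raise ConfigError(
                "collection_completeness_probs", "need three nonnegative probabilities"
            )
        total = sum(probs)
        # the published shares sum to 0.99; tolerate rounding, renormalize later
        if abs(total - 1.0) > 0.05:
            raise ConfigError(
                "collection_completeness_probs", f"probabilities sum to {total}, expected ~1"
            )
        if self.lambda_x < 0:
            raise ConfigError("lambda_x", "must be >= 0")
        if not 0.0 <= self.ffq_item_noise <= 1.0:
            raise ConfigError("ffq_item_noise", "must be a probability in [0, 1]")
        if self.fci_error_sd < 0:
            raise ConfigError("fci_error_sd", "must be >= 0")
        if self.group_intake_noise_sd < 0:
            raise ConfigError("group_intake_noise_sd", "must be >= 0")
        if not 0.0 <= self.single_miss_prob <= 1.0:
            raise ConfigError("single_miss_prob", "must be a probability in [0, 1]")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ConfigError("dropout_prob", "must be a probability in [0, 1]")
        if not 0.0 <= self.behavior_corr < 1.0:
            raise ConfigError("behavior_corr", "must lie in [0, 1)")

    @property
    def completeness_probs_normalized(self) -> tuple[float, float, float]:
        probs = tuple(float(p) for p in self.collection_completeness_probs)
        total = sum(probs)
        return tuple(p / total for p in probs)  # type: ignore[return-value]


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings: selection thresholds, split, outputs."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    #: trend-significance threshold used for variable selection
    alpha: float = 0.05
    stepwise_entry: float = 0.05
    stepwise_stay: float = 0.05
    split_seed: int | None = None
    include_characteristics: bool = True
    energy_adjust_method: str = "residual"  # residual | density | none
    #: n used in the deattenuation factor: "mean" complete collections, or "fixed"
    deattenuate_n: str = "mean"
    fixed_n_collections: int = 5
    use_pearson: bool = False
    #: drop antihypertensive-medication users before validation correlations
    exclude_htn_med: bool = False
    run_ffq1_replication: bool = True
    make_plots: bool = False
    output_dir: str | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha", "must lie strictly between 0 and 1")
        for name in ("stepwise_entry", "stepwise_stay"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(name, "must lie strictly between 0 and 1")
        if self.energy_adjust_method not in ("residual", "density", "none"):
            raise ConfigError("energy_adjust_method", "must be residual, density or none")
        if self.deattenuate_n not in ("mean", "fixed"):
            raise ConfigError("deattenuate_n", "must be 'mean' or 'fixed'")
        if self.fixed_n_collections < 1:
            raise ConfigError("fixed_n_collections", "must be >= 1")
        if not isinstance(self.cohort, CohortConfig):
            raise ConfigError("cohort", "must be a CohortConfig")

    @property
    def effective_split_seed(self) -> int:
        return self.cohort.seed + 1 if self.split_seed is None else self.split_seed

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["true_weights_na"] = dict(self.cohort.true_weights_na)
        d["cohort"]["true_weights_nak"] = dict(self.cohort.true_weights_nak)
        d["cohort"]["collection_completeness_probs"] = list(
            self.cohort.collection_completeness_probs
        )
        return d


def load_pipeline_config(path) -> PipelineConfig:
    """Read a :class:`PipelineConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_raw = raw.pop("cohort", {}) or {}
    if "collection_completeness_probs" in cohort_raw:
        cohort_raw["collection_completeness_probs"] = tuple(
            cohort_raw["collection_completeness_probs"]
        )
    try:
        cohort = CohortConfig(**cohort_raw)
        return PipelineConfig(cohort=cohort, **raw)
    except TypeError as exc:  # unknown key
        raise ConfigError("<yaml>", str(exc)) from exc


def dump_pipeline_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
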