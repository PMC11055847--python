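import numpy as np
import pandas as pd
import pytest

from saltscore import CohortConfig
from saltscore.pipeline import _analysis_frame
from saltscore.synthetic import generate_cohort
from saltscore.urine import summarize_excretion


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def default_analysis_frame(default_cohort):
    summary, _ = summarize_excretion(default_cohort.urine_days)
    return _analysis_frame(default_cohort.ffq, "FFQ2",
                           default_cohort.participants, summary)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def noise_free_config(seed: int = 3, **overrides) -> CohortConfig:
    """Cohort whose observed data equal the latent truth exactly."""
    kwargs = dict(
        n_participants=244, lambda_x=0.0, ffq_item_noise=0.0,
        group_intake_noise_sd=0.0, fci_error_sd=0.0, single_miss_prob=0.0,
        dropout_prob=0.0, seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def analysis_frame_for(cohort, instrument="FFQ2") -> pd.DataFrame:
    summary, _ = summarize_excretion(cohort.urine_days)
    return _analysis_frame(cohort.ffq, instrument, cohort.participants, summary)
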