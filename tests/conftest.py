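import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic synthetic cohort at desk scale."""
    from paceline.config import GeneratorConfig
    from paceline.synthetic import generate_cohort

    cfg = GeneratorConfig(n_individuals=40, sessions_per_individual=2,
                          survival_prob=1.0, rng_seed=11)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    from paceline.growth import add_birth_columns
    from paceline.inference import prepare_analysis_table

    cohort, _ = small_cohort
    return prepare_analysis_table(add_birth_columns(cohort, intervals=()))


@pytest.fixture()
def rng():
    return np.random.default_rng(314159)


def balanced_anova_icc(values: np.ndarray, groups: np.ndarray) -> float:
    """Method-of-moments ICC for a balanced one-way design (oracle)."""
    df = pd.DataFrame({"y": values, "g": groups})
    k = df.groupby("g").size().iloc[0]
    msb = k * df.groupby("g")["y"].mean().var(ddof=1)
    msw = df.groupby("g")["y"].var(ddof=1).mean()
    s_ind = (msb - msw) / k
    return s_ind / (s_ind + msw)
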