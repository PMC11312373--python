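import numpy as np
import pandas as pd
import pytest

from inflascore import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 4,000-participant cohort under default study conditions."""
    return generate_cohort(CohortConfig(n_participants=4000, seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def simulate_exponential_survival(
    rng, n, log_hr_per_group, censor_years=13.0, base_rate=0.02
):
    """Two-or-more group exponential survival data with known rate ratios.

    Returns a DataFrame with ``group`` (categorical Q1..Qk), ``time`` and
    ``event``.  The closed-form rate ratio between groups g and reference
    is exp(log_hr[g]).
    """
    k = len(log_hr_per_group)
    group = rng.integers(0, k, n)
    lp = np.asarray(log_hr_per_group)[group]
    t = rng.exponential(1.0 / (base_rate * np.exp(lp)))
    event = (t <= censor_years).astype(int)
    time = np.minimum(t, censor_years)
    labels = [f"Q{i + 1}" for i in range(k)]
    return pd.DataFrame(
        {
            "group": pd.Categorical(
                [labels[g] for g in group], categories=labels, ordered=True
            ),
            "time": time,
            "event": event,
        }
    )
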