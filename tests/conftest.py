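import numpy as np
import pandas as pd
import pytest

from schoolenv import SimConfig, generate_study


@pytest.fixture(scope="session")
def small_config():
    """Four weeks, twenty schools: fast but covers both seasons."""
    return SimConfig(
        n_schools=20,
        n_fixed_sites=6,
        weeks=4,
        harmattan_weeks=frozenset({3, 4}),
        seed=20220606,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def week_index():
    """One complete Monday-to-Monday week of minutes."""
    return pd.date_range("2022-06-06", periods=10080, freq="min")


def brute_force_leq(values):
    """Independent energy-mean oracle used across the noise tests."""
    e = [10.0 ** (v / 10.0) for v in np.asarray(values, dtype=float)]
    return 10.0 * np.log10(sum(e) / len(e))
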