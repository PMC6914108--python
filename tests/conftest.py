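import numpy as np
import pytest

from cardmatch.simulate import generate_cohort, scenario


@pytest.fixture(scope="session")
def small_cohort():
    """A confounded 400-patient cohort shared by read-only tests."""
    cohort, truth = generate_cohort(scenario("paper-like", 400, seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def tiny_cohort():
    cohort, _ = generate_cohort(scenario("paper-like", 60, seed=4))
    return cohort


def random_instance(rng: np.random.Generator, n_treated: int, n_control: int):
    """A minimal one-covariate cohort for exhaustive matching oracles."""
    import pandas as pd

    n = n_treated + n_control
    df = pd.DataFrame({
        "id": np.arange(n),
        "treated": np.r_[np.ones(n_treated, int), np.zeros(n_control, int)],
        "age": np.round(rng.normal(65, 10, n), 1),
        "income": np.round(rng.normal(65000, 30000, n), 0),
        "sex": rng.choice(["female", "male"], n),
        "race": rng.choice(["white", "black", "hispanic", "other"], n),
        "insurance": rng.choice(["commercial", "medicaid", "medicare", "none"], n),
        "prov_faculty": rng.integers(0, 2, n),
        "prov_physician": rng.integers(0, 2, n),
        "prov_male": rng.integers(0, 2, n),
        "flu": rng.integers(0, 2, n),
        "bp_test": rng.integers(0, 2, n),
        "ldl_test": rng.integers(0, 2, n),
        "crc_test": rng.integers(0, 2, n),
        "sbp": rng.normal(130, 15, n),
        "ldl": rng.normal(110, 30, n),
        "diabetes": rng.integers(0, 2, n),
        "hypertension": rng.integers(0, 2, n),
    })
    return df
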