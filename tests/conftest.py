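import warnings

import numpy as np
import pandas as pd
import pytest

import cohortdag as cd

# MDLP legitimately drops no-cut columns in several fixtures; keep logs quiet.
warnings.filterwarnings("ignore", message="MDLP accepted no cut")


@pytest.fixture(scope="session")
def toy_specs():
    return cd.load_specs(
        [
            {"name": "age", "scale": "continuous"},
            {
                "name": "sleep_duration",
                "scale": "ordinal",
                "levels": ["<6 hours", "6-8 hours", ">8 hours"],
            },
            {"name": "diet", "scale": "nominal", "levels": ["Non-vegetarian", "Vegetarian"]},
            {"name": "hypertension", "scale": "binary", "levels": ["absent", "present"]},
            {"name": "died", "scale": "binary", "levels": ["no", "yes"], "outcome": True},
        ]
    )


@pytest.fixture(scope="session")
def toy_raw():
    return pd.DataFrame(
        {
            "age": [50, 61, 47, 55],
            "sleep_duration": ["<6 hours", "6-8 hours", ">8 hours", "6-8 hours"],
            "diet": ["Non-vegetarian", "Vegetarian", "Non-vegetarian", "Vegetarian"],
            "hypertension": ["absent", "present", "absent", "present"],
            "died": ["no", "yes", "no", "no"],
        }
    )


@pytest.fixture(scope="session")
def chain3_data():
    """n=1000 draws of A -> B (1.5) -> C (-1.0), noise SD 1, fixed seed."""
    rng = np.random.default_rng(42)
    n = 1000
    a = rng.normal(size=n)
    b = 1.5 * a + rng.normal(size=n)
    c = -1.0 * b + rng.normal(size=n)
    return np.column_stack([a, b, c])


@pytest.fixture(scope="session")
def stemilike_dataset():
    sem = cd.default_stemilike_spec(seed=11)
    ds, truth = cd.generate(sem, 1500)
    return ds, truth
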