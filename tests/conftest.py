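import numpy as np
import pandas as pd
import pytest

import mealprint as mp


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small simulated cohort shared by read-only tests."""
    cfg = mp.default_config({"HC": 40, "mild": 25, "moderate_severe": 15}, seed=7)
    survey, log, truth = mp.generate_cohort(cfg)
    return cfg, survey, log, truth


@pytest.fixture(scope="session")
def tiny_meals(tiny_cohort):
    cfg, survey, log, _ = tiny_cohort
    seg = mp.MealSegmenter()
    meals = seg.fit_transform(log)
    return cfg, survey, meals


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_transactions(times, student="S1", date="2020-10-05", amount=5.0,
                      cafeteria=1, items=None):
    """Helper: transaction frame for one student-day from a list of times."""
    items = items or [f"C{cafeteria}-I{i:02d}" for i in range(len(times))]
    return pd.DataFrame({
        "student_id": student, "date": date, "time": list(times),
        "amount": amount if np.ndim(amount) else [amount] * len(times),
        "cafeteria_id": cafeteria, "item_id": items,
    })
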