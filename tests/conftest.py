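import numpy as np
import pandas as pd
import pytest

from growthtrack import (
    ErrorRates,
    SyntheticConfig,
    UnitMix,
    generate_cohort,
    synthetic_reference,
)


@pytest.fixture(scope="session")
def reference():
    return synthetic_reference()


@pytest.fixture(scope="session")
def bmi_row(reference):
    return reference.interpolate("male", 60.0, "bmi")


def visits_frame(rows):
    """Build a schema-shaped visit table from
    (child_id, sex, birth_year, exam_date, wv, wu, hv, hu) tuples."""
    df = pd.DataFrame(
        rows,
        columns=[
            "child_id",
            "sex",
            "birth_year",
            "exam_date",
            "weight_value",
            "weight_unit",
            "height_value",
            "height_unit",
        ],
    )
    df["exam_date"] = pd.to_datetime(df["exam_date"])
    df.insert(0, "record_id", np.arange(len(df)))
    return df


@pytest.fixture(scope="session")
def clean_metric_config():
    """All-metric, error-free generator settings (benign noise only)."""
    return SyntheticConfig(
        n_children=800,
        seed=11,
        unit_mix=UnitMix(us_standard=0.0, metric=1.0, mismatched=0.0),
        error_rates=ErrorRates.none(),
        high_utilizer_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_corrupted_cohort():
    return generate_cohort(SyntheticConfig(n_children=400, seed=5))
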