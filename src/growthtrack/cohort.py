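"""Cohort construction: eligibility, ages, exam pairs and age windows.

EHR extracts often carry only the examination date and the year of
birth, so age is estimated from the midpoint of the birth year (July 1)
using a 365.25-day year.  The tracking design pairs each child's first
eligible examination (age 2 to <10 y) with the last examination at
least one year later; a secondary design requires visits in three age
windows (2 to <4 y, 6 to <8 y, >=10 y).  For prevalence estimation one
record is sampled per child within each age-group x calendar-year cell
so high utilizers do not dominate.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import norm

from .growth_reference import LMSReference, lms_inverse_arrays, lms_zscore_arrays

__all__ = [
    "DAYS_PER_YEAR",
    "estimate_age",
    "estimate_ages",
    "attach_bmi_metrics",
    "select_first_last",
    "extract_three_windows",
    "sample_one_per_cell",
    "PAIR_COLUMNS",
]

DAYS_PER_YEAR = 365.25

PAIR_COLUMNS = [
    "child_id",
    "sex",
    "first_age",
    "first_date",
    "first_bmi",
    "first_bmiz",
    "first_obese",
    "last_age",
    "last_date",
    "last_bmi",
    "last_bmiz",
    "last_obese",
    "interval_years",
]

_WINDOWS = {"w1": (2.0, 4.0), "w2": (6.0, 8.0), "w3": (10.0, np.inf)}


def estimate_age(exam_date: Union[str, dt.date, pd.Timestamp], birth_year: int) -> float:
    """Age in years from the exam date and the midpoint (July 1) of the
    birth year, using a 365.25-day year.  Negative ages are rejected."""
    exam = pd.Timestamp(exam_date)
    age = (exam - pd.Timestamp(int(birth_year), 7, 1)).days / DAYS_PER_YEAR
    if age < 0:
        raise ValueError(
            f"examination {exam.date()} precedes midpoint of birth year {birth_year}"
        )
    return float(age)


def estimate_ages(exam_dates: pd.Series, birth_years) -> np.ndarray:
    """Vectorized :func:`estimate_age` (no rejection; caller screens)."""
    exam = pd.to_datetime(exam_dates)
    mid = pd.to_datetime(
        {"year": np.asarray(birth_years, dtype=int), "month": 7, "day": 1}
    )
    days = (exam.to_numpy() - mid.to_numpy()).astype("timedelta64[D]").astype(float)
    return days / DAYS_PER_YEAR


def attach_bmi_metrics(
    records: pd.DataFrame, reference: LMSReference
) -> pd.DataFrame:
    """Add ``age_years`` (if absent), ``bmi``, ``bmiz`` and ``obese`` /
    ``severe_obese`` columns to a metric-unit record table.

    Expects ``weight_kg`` and ``height_cm`` columns (as produced by the
    cleaning pipeline) or metric ``weight_value`` / ``height_value``.
    """
    df = records.copy()
    if "weight_kg" not in df.columns:
        if not (df["weight_unit"] == "kg").all() or not (df["height_unit"] == "cm").all():
            raise ValueError("attach_bmi_metrics expects metric units")
        df["weight_kg"] = df["weight_value"].astype(float)
        df["height_cm"] = df["height_value"].astype(float)
    if "age_years" not in df.columns:
        df["age_years"] = estimate_ages(df["exam_date"], df["birth_year"])
    df["bmi"] = df["weight_kg"] / (df["height_cm"] / 100.0) ** 2
    L, M, S = reference.params_mixed(
        df["sex"].to_numpy(), df["age_years"].to_numpy() * 12.0, "bmi"
    )
    df["bmiz"] = lms_zscore_arrays(df["bmi"].to_numpy(), L, M, S)
    p95 = lms_inverse_arrays(norm.ppf(0.95), L, M, S)
    df["obese"] = df["bmi"].to_numpy() >= p95
    df["severe_obese"] = df["bmi"].to_numpy() >= 1.2 * p95
    return df


def select_first_last(
    records: pd.DataFrame,
    first_age_range: tuple[float, float] = (2.0, 10.0),
    min_interval_years: float = 1.0,
) -> pd.DataFrame:
    """First/last exam pairs for every eligible child.

    The first exam is the earliest retained visit with age in
    ``[first_age_range)``; the last exam is the child's latest retained
    visit, and the pair is eligible only when it falls at least
    ``min_interval_years`` after the first.  Ineligible children are
    simply absent from the output (ineligibility is a value, not an
    error).  Expects the columns added by :func:`attach_bmi_metrics`.
    """
    needed = {"child_id", "sex", "exam_date", "age_years", "bmi", "bmiz", "obese"}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    df = records.sort_values(["child_id", "exam_date"], kind="stable")
    lo, hi = first_age_range
    eligible_first = df[(df["age_years"] >= lo) & (df["age_years"] < hi)]
    first = eligible_first.groupby("child_id", sort=False).head(1)
    last = df.groupby("child_id", sort=False).tail(1)
    pairs = first.merge(
        last, on="child_id", suffixes=("_first", "_last"), how="inner"
    )
    interval = pairs["age_years_last"] - pairs["age_years_first"]
    pairs = pairs[interval >= min_interval_years]
    out = pd.DataFrame(
        {
            "child_id": pairs["child_id"].to_numpy(),
            "sex": pairs["sex_first"].to_numpy(),
            "first_age": pairs["age_years_first"].to_numpy(),
            "first_date": pairs["exam_date_first"].to_numpy(),
            "first_bmi": pairs["bmi_first"].to_numpy(),
            "first_bmiz": pairs["bmiz_first"].to_numpy(),
            "first_obese": pairs["obese_first"].to_numpy(),
            "last_age": pairs["age_years_last"].to_numpy(),
            "last_date": pairs["exam_date_last"].to_numpy(),
            "last_bmi": pairs["bmi_last"].to_numpy(),
            "last_bmiz": pairs["bmiz_last"].to_numpy(),
            "last_obese": pairs["obese_last"].to_numpy(),
        }
    )
    out["interval_years"] = out["last_age"] - out["first_age"]
    return out.reset_index(drop=True)


def extract_three_windows(records: pd.DataFrame) -> pd.DataFrame:
    """Earliest retained visit in each of the 2-<4 y, 6-<8 y and >=10 y
    windows; children missing any window are absent from the output."""
    needed = {"child_id", "exam_date", "age_years", "bmiz", "obese"}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    df = records.sort_values(["child_id", "exam_date"], kind="stable")
    parts = []
    for name, (lo, hi) in _WINDOWS.items():
        sel = df[(df["age_years"] >= lo) & (df["age_years"] < hi)]
        block = sel.groupby("child_id", sort=False).head(1)
        block = block[["child_id", "age_years", "bmiz", "obese"]].rename(
            columns={
                "age_years": f"{name}_age",
                "bmiz": f"{name}_bmiz",
                "obese": f"{name}_obese",
            }
        )
        parts.append(block)
    out = parts[0]
    for block in parts[1:]:
        out = out.merge(block, on="child_id", how="inner")
    return out.reset_index(drop=True)


def sample_one_per_cell(
    records: pd.DataFrame,
    age_bins: Sequence[float],
    year_bins: Optional[Sequence[int]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """At most one record per (child, age-group, year-bin) cell, selected
    uniformly at random; reproducible from ``seed``.

    ``age_bins`` are half-open edges for :func:`pandas.cut` (e.g.
    ``[2, 6, 12]`` for 2-<6 and 6-<12).  ``year_bins`` optionally groups
    calendar years the same way; by default each calendar year is its
    own bin.  Records outside the bins are dropped.
    """
    df = records.copy()
    df["_age_group"] = pd.cut(df["age_years"], bins=list(age_bins), right=False)
    years = pd.to_datetime(df["exam_date"]).dt.year
    if year_bins is None:
        df["_year_bin"] = years
    else:
        df["_year_bin"] = pd.cut(years, bins=list(year_bins), right=False)
    df = df.dropna(subset=["_age_group", "_year_bin"])
    rng = np.random.default_rng(seed)
    df = df.iloc[rng.permutation(len(df))]
    df = df.drop_duplicates(subset=["child_id", "_age_group", "_year_bin"])
    df = df.rename(columns={"_age_group": "age_group", "_year_bin": "year_bin"})
    return df.sort_values(["child_id", "exam_date"], kind="stable").reset_index(drop=True)
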