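"""LMS growth-reference computations.

Pediatric anthropometry is referenced against sex- and age-specific
distributions summarized by three parameters: a Box-Cox power ``L`` that
normalizes the skewed measurement distribution, the median ``M``, and a
coefficient of variation ``S``.  A measurement ``X`` maps to a z-score

    z = ((X / M)**L - 1) / (L * S)          (L != 0)
    z = ln(X / M) / S                       (L == 0)

and percentiles follow from the normal CDF.  This module provides the
forward and inverse transforms, the robust "modified" z-score used for
error screening (distance from the median in units of half the distance
between the median and the +/-2 SD reference values), BMI computation,
obesity classification (BMI at or above the 95th reference percentile;
severe obesity at or above 120% of that cutoff), and age interpolation of
a tabulated reference.

The shipped :func:`synthetic_reference` builds a smooth, internally
consistent reference table with realistic magnitudes.  It is synthetic:
none of its values are taken from any published growth chart.  Any real
LMS table in the documented CSV schema can be loaded instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "LB_TO_KG",
    "IN_TO_CM",
    "SEXES",
    "MEASURES",
    "LMSRow",
    "ZScoreResult",
    "ObesityStatus",
    "LMSReference",
    "synthetic_reference",
    "lms_zscore",
    "lms_inverse",
    "modified_zscore",
    "zscore_result",
    "bmi",
    "obesity_cutoff",
    "classify_obesity",
    "lms_zscore_arrays",
    "lms_inverse_arrays",
    "modified_zscore_arrays",
]

LB_TO_KG = 0.45359237
IN_TO_CM = 2.54

SEXES = ("male", "female")
MEASURES = ("bmi", "weight", "height")

# |L| below this uses the logarithmic limit of the LMS transform
# (removable singularity at L = 0).
_L_LOG_SWITCH = 1e-8

_REFERENCE_COLUMNS = ["sex", "measure", "age_months", "L", "M", "S"]


@dataclass(frozen=True)
class LMSRow:
    """One (sex, age, measure) entry of an LMS reference.

    ``L`` is the unitless Box-Cox power, ``M`` the median in measurement
    units, ``S`` the unitless coefficient of variation.
    """

    sex: str
    age_months: float
    measure: str
    L: float
    M: float
    S: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.measure not in MEASURES:
            raise ValueError(
                f"measure must be one of {MEASURES}, got {self.measure!r}"
            )
        if not (np.isfinite(self.L) and np.isfinite(self.M) and np.isfinite(self.S)):
            raise ValueError("L, M, S must be finite")
        if self.M <= 0:
            raise ValueError(f"M must be positive, got {self.M}")
        if self.S <= 0:
            raise ValueError(f"S must be positive, got {self.S}")


@dataclass(frozen=True)
class ZScoreResult:
    """z-score, percentile (= 100*Phi(z)) and modified z for one value."""

    z: float
    percentile: float
    modified_z: float


class ObesityStatus(str, Enum):
    NOT_OBESE = "not_obese"
    OBESE = "obese"
    SEVERE = "severe"

    @property
    def is_obese(self) -> bool:
        return self is not ObesityStatus.NOT_OBESE


# ---------------------------------------------------------------------------
# vectorized core (arrays of values with matching L/M/S arrays)
# ---------------------------------------------------------------------------


def lms_zscore_arrays(values, L, M, S):
    """Vectorized LMS z-score; ``values`` must be positive."""
    values = np.asarray(values, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(values <= 0):
        raise ValueError("measurement values must be positive")
    ratio = values / M
    log_branch = np.abs(L) < _L_LOG_SWITCH
    # expm1(L*ln(v/M)) keeps precision as L -> 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z_pow = np.expm1(np.where(log_branch, 1.0, L) * np.log(ratio)) / (
            np.where(log_branch, 1.0, L) * S
        )
    z_log = np.log(ratio) / S
    return np.where(log_branch, z_log, z_pow)


def lms_inverse_arrays(z, L, M, S):
    """Vectorized inverse of :func:`lms_zscore_arrays`.

    Requires ``1 + L*S*z > 0`` wherever ``L != 0``.
    """
    z = np.asarray(z, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    log_branch = np.abs(L) < _L_LOG_SWITCH
    t = 1.0 + L * S * z
    if np.any(~log_branch & (t <= 0)):
        raise ValueError(
            "z outside the domain of the LMS inverse (1 + L*S*z must be > 0)"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        v_pow = M * np.exp(
            np.log1p(np.where(log_branch, 0.0, L * S * z)) / np.where(log_branch, 1.0, L)
        )
    v_log = M * np.exp(S * z)
    return np.where(log_branch, v_log, v_pow)


def modified_zscore_arrays(values, L, M, S):
    """Vectorized modified z-score.

    Distance from the median in units of half the distance between the
    median and the +2 SD reference value (above the median) or the -2 SD
    value (below).  Equals +/-2 exactly at the z = +/-2 reference values.
    """
    values = np.asarray(values, dtype=float)
    M = np.asarray(M, dtype=float)
    up = (lms_inverse_arrays(2.0, L, M, S) - M) / 2.0
    dn = (M - lms_inverse_arrays(-2.0, L, M, S)) / 2.0
    half_sd = np.where(values >= M, up, dn)
    return (values - M) / half_sd


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------


def _check_value(value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"measurement value must be positive and finite, got {value}")
    return value


def lms_zscore(value: float, row: LMSRow) -> float:
    """z-score of ``value`` (measurement units) against ``row``."""
    value = _check_value(value)
    return float(lms_zscore_arrays(value, row.L, row.M, row.S))


def lms_inverse(z: float, row: LMSRow) -> float:
    """Measurement value whose z-score against ``row`` equals ``z``."""
    return float(lms_inverse_arrays(float(z), row.L, row.M, row.S))


def modified_zscore(value: float, row: LMSRow) -> float:
    """Modified (half-SD-unit) z-score of ``value`` against ``row``."""
    value = _check_value(value)
    return float(modified_zscore_arrays(value, row.L, row.M, row.S))


def zscore_result(value: float, row: LMSRow) -> ZScoreResult:
    z = lms_zscore(value, row)
    return ZScoreResult(
        z=z,
        percentile=float(100.0 * norm.cdf(z)),
        modified_z=modified_zscore(value, row),
    )


def bmi(weight_kg: float, height_cm: float) -> float:
    """Body-mass index, kg/m^2."""
    weight_kg = float(weight_kg)
    height_cm = float(height_cm)
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    return weight_kg / (height_cm / 100.0) ** 2


def obesity_cutoff(row: LMSRow, percentile: float = 95.0) -> float:
    """Measurement value at the given reference percentile."""
    return lms_inverse(norm.ppf(percentile / 100.0), row)


def classify_obesity(bmi_value: float, row: LMSRow) -> ObesityStatus:
    """Obesity category for a BMI value against a BMI reference row.

    Obesity: BMI at or above the 95th percentile.  Severe obesity: BMI at
    or above 120% of the 95th-percentile value.  Both cutoffs inclusive.
    """
    if row.measure != "bmi":
        raise ValueError(f"classify_obesity requires a BMI row, got {row.measure!r}")
    bmi_value = _check_value(bmi_value)
    p95 = obesity_cutoff(row)
    if bmi_value >= 1.2 * p95:
        return ObesityStatus.SEVERE
    if bmi_value >= p95:
        return ObesityStatus.OBESE
    return ObesityStatus.NOT_OBESE


# ---------------------------------------------------------------------------
# reference table
# ---------------------------------------------------------------------------


class LMSReference:
    """A sex- and age-indexed LMS table for BMI, weight and height.

    Wraps a DataFrame with columns ``sex, measure, age_months, L, M, S``;
    ages must be strictly increasing within each (sex, measure) block.
    Parameters at arbitrary ages are obtained by linear interpolation of
    L, M and S separately between the bracketing tabulated ages (exact at
    the knots).
    """

    def __init__(self, table: pd.DataFrame):
        missing = set(_REFERENCE_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"reference table missing columns: {sorted(missing)}")
        table = table.loc[:, _REFERENCE_COLUMNS].copy()
        table["age_months"] = table["age_months"].astype(float)
        for col in ("L", "M", "S"):
            table[col] = table[col].astype(float)
        bad_sex = set(table["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex codes in reference: {sorted(bad_sex)}")
        bad_measure = set(table["measure"]) - set(MEASURES)
        if bad_measure:
            raise ValueError(f"unknown measures in reference: {sorted(bad_measure)}")
        if (table["M"] <= 0).any() or (table["S"] <= 0).any():
            raise ValueError("M and S must be positive throughout the reference")
        table = table.sort_values(["sex", "measure", "age_months"], kind="stable")
        self._table = table.reset_index(drop=True)
        self._grids: dict[tuple[str, str], tuple[np.ndarray, ...]] = {}
        for (sex, measure), block in self._table.groupby(["sex", "measure"]):
            ages = block["age_months"].to_numpy()
            if np.any(np.diff(ages) <= 0):
                raise ValueError(
                    f"ages must be strictly increasing within ({sex}, {measure})"
                )
            self._grids[(sex, measure)] = (
                ages,
                block["L"].to_numpy(),
                block["M"].to_numpy(),
                block["S"].to_numpy(),
            )

    @property
    def table(self) -> pd.DataFrame:
        return self._table.copy()

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "LMSReference":
        return cls(pd.read_csv(path))

    def to_csv(self, path: Union[str, Path]) -> None:
        self._table.to_csv(path, index=False)

    def age_range(self, sex: str, measure: str) -> tuple[float, float]:
        ages = self._grid(sex, measure)[0]
        return float(ages[0]), float(ages[-1])

    def _grid(self, sex: str, measure: str):
        try:
            return self._grids[(sex, measure)]
        except KeyError:
            raise KeyError(f"reference has no block for ({sex!r}, {measure!r})") from None

    def interpolate(self, sex: str, age_months: float, measure: str) -> LMSRow:
        """LMS parameters at ``age_months``, linearly interpolated."""
        L, M, S = self.params(sex, np.asarray([float(age_months)]), measure)
        return LMSRow(
            sex=sex,
            age_months=float(age_months),
            measure=measure,
            L=float(L[0]),
            M=float(M[0]),
            S=float(S[0]),
        )

    def params(self, sex: str, ages_months: np.ndarray, measure: str):
        """Vectorized interpolation for one sex; ages in months."""
        ages_months = np.asarray(ages_months, dtype=float)
        grid_ages, gl, gm, gs = self._grid(sex, measure)
        lo, hi = grid_ages[0], grid_ages[-1]
        if ages_months.size and (
            np.min(ages_months) < lo or np.max(ages_months) > hi
        ):
            raise ValueError(
                f"age out of reference range [{lo}, {hi}] months for "
                f"({sex}, {measure}): "
                f"[{np.min(ages_months):.2f}, {np.max(ages_months):.2f}]"
            )
        return (
            np.interp(ages_months, grid_ages, gl),
            np.interp(ages_months, grid_ages, gm),
            np.interp(ages_months, grid_ages, gs),
        )

    def params_mixed(self, sexes: np.ndarray, ages_months: np.ndarray, measure: str):
        """Vectorized interpolation for an array mixing both sexes."""
        sexes = np.asarray(sexes)
        ages_months = np.asarray(ages_months, dtype=float)
        L = np.empty_like(ages_months)
        M = np.empty_like(ages_months)
        S = np.empty_like(ages_months)
        for sex in SEXES:
            mask = sexes == sex
            if mask.any():
                L[mask], M[mask], S[mask] = self.params(
                    sex, ages_months[mask], measure
                )
        unknown = ~np.isin(sexes, SEXES)
        if unknown.any():
            raise ValueError(f"unknown sex codes: {sorted(set(sexes[unknown]))}")
        return L, M, S


def interpolate_lms(
    reference: LMSReference, sex: str, age_months: float, measure: str
) -> LMSRow:
    """Functional alias for :meth:`LMSReference.interpolate`."""
    return reference.interpolate(sex, age_months, measure)


def synthetic_reference(
    age_min_months: int = 18, age_max_months: int = 240, step_months: int = 3
) -> LMSReference:
    """A smooth synthetic LMS table covering ages 1.5-20 y, both sexes.

    Median BMI dips in early childhood and rises through adolescence;
    median height rises monotonically with a decelerating velocity; the
    weight medians are derived from the BMI and height medians so the
    three measures are mutually consistent.  Magnitudes are chosen to be
    physiologically plausible, but every value is synthetic.
    """
    ages = np.arange(age_min_months, age_max_months + 1, step_months, dtype=float)
    years = ages / 12.0
    rows = []
    for sex in SEXES:
        girl = sex == "female"
        m_bmi = np.where(
            years >= 5.0,
            15.5 + 0.018 * (years - 5.0) ** 2,
            15.5 + 0.07 * (5.0 - years) ** 2,
        ) - (0.15 if girl else 0.0)
        l_bmi = (-2.1 if girl else -2.0) - 0.01 * (years - 2.0)
        s_bmi = 0.085 + 0.0028 * (years - 2.0)
        if girl:
            m_hgt = 86.0 + 88.0 * (1.0 - np.exp(-0.125 * (years - 2.0 + 1e-9)))
        else:
            m_hgt = 86.0 + 95.0 * (1.0 - np.exp(-0.115 * (years - 2.0 + 1e-9)))
        # below age 2 the exponential argument goes negative; keep monotone
        m_hgt = np.where(
            years < 2.0, 86.0 - 12.0 * (2.0 - years), m_hgt
        )
        l_hgt = np.full_like(years, 1.0)
        s_hgt = np.full_like(years, 0.042 if girl else 0.040)
        m_wgt = m_bmi * (m_hgt / 100.0) ** 2
        l_wgt = np.full_like(years, -1.2)
        s_wgt = 0.11 + 0.004 * (years - 2.0)
        for measure, L, M, S in (
            ("bmi", l_bmi, m_bmi, s_bmi),
            ("height", l_hgt, m_hgt, s_hgt),
            ("weight", l_wgt, m_wgt, s_wgt),
        ):
            rows.append(
                pd.DataFrame(
                    {
                        "sex": sex,
                        "measure": measure,
                        "age_months": ages,
                        "L": L,
                        "M": M,
                        "S": S,
                    }
                )
            )
    return LMSReference(pd.concat(rows, ignore_index=True))
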