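"""Synthetic longitudinal EHR generator.

Builds visit tables with the statistical structure the tracking analysis
assumes -- children first seen between ages 2 and 9 years, a handful of
visits spread over several years, a latent BMI-for-age z-score (BMIz)
that follows a stationary continuous-time AR(1) process (so the
first-to-last correlation is ``rho**gap_years``), obesity prevalence that
rises with age, and weights/heights recorded in a mix of US-standard and
metric units -- plus controlled injection of the error modes a cleaning
pipeline must detect: carried-forward values, unit swaps, transcription
errors (decimal shifts and digit transpositions) and same-day duplicate
rows.

Ground truth (latent values and error labels) is returned in side tables
keyed by ``record_id`` so that cleaning can be evaluated while remaining
blind to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq
from scipy.stats import norm

from .growth_reference import (
    IN_TO_CM,
    LB_TO_KG,
    LMSReference,
    lms_inverse_arrays,
    synthetic_reference,
)

__all__ = [
    "UnitMix",
    "ErrorRates",
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_cohort",
    "inject_errors",
    "VISIT_COLUMNS",
]

VISIT_COLUMNS = [
    "record_id",
    "child_id",
    "sex",
    "birth_year",
    "exam_date",
    "weight_value",
    "weight_unit",
    "height_value",
    "height_unit",
]

LABEL_COLUMNS = ["record_id", "child_id", "exam_date", "measure", "error_mode", "true_value"]


class UnitMix(BaseModel):
    """Proportions of children whose records use each unit system."""

    us_standard: float = Field(0.90, ge=0.0, le=1.0)
    metric: float = Field(0.06, ge=0.0, le=1.0)
    mismatched: float = Field(0.04, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _sums_to_one(self) -> "UnitMix":
        total = self.us_standard + self.metric + self.mismatched
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"unit mix must sum to 1, got {total}")
        return self


class ErrorRates(BaseModel):
    """Per-measurement corruption probabilities.

    ``transcription`` applies independently to weights and heights and
    splits evenly between decimal shifts (x10 or /10) and adjacent-digit
    transpositions.  ``same_day_duplicate`` is the probability that a
    visit spawns an extra row on the same date with perturbed values.
    """

    carried_forward_weight: float = Field(0.05, ge=0.0, le=1.0)
    carried_forward_height: float = Field(0.06, ge=0.0, le=1.0)
    unit_swap: float = Field(0.003, ge=0.0, le=1.0)
    transcription: float = Field(0.004, ge=0.0, le=1.0)
    same_day_duplicate: float = Field(0.005, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _per_measurement_sums(self) -> "ErrorRates":
        w = self.carried_forward_weight + self.unit_swap + self.transcription
        h = self.carried_forward_height + self.transcription
        if w > 1.0 or h > 1.0:
            raise ValueError(
                "per-measurement error rates must sum to at most 1 "
                f"(weight modes: {w}, height modes: {h})"
            )
        return self

    @classmethod
    def none(cls) -> "ErrorRates":
        return cls(
            carried_forward_weight=0.0,
            carried_forward_height=0.0,
            unit_swap=0.0,
            transcription=0.0,
            same_day_duplicate=0.0,
        )


class SyntheticConfig(BaseModel):
    """Generator parameters.

    Defaults emulate the study conditions of a large ambulatory pediatric
    EHR cohort: ~6.5 visits per child, mean first-to-last follow-up of
    ~4 years, first exams uniform over ages 2-9 y, 48% girls, first-exam
    obesity prevalence 13.4% rising with age, and a per-year latent BMIz
    autocorrelation chosen so the correlation over a typical 3.7-year
    follow-up is 0.80.
    """

    n_children: int = Field(..., ge=1)
    seed: int = 0
    first_age_range: tuple[float, float] = (2.0, 9.0)
    visits_mean: float = Field(6.5, gt=1.0)
    visits_max: int = Field(30, ge=1)
    gap_mean_years: float = Field(0.73, gt=0.0)
    max_age_years: float = Field(19.0, gt=0.0)
    tracking_rho_per_year: float = Field(0.8 ** (1.0 / 3.7), gt=0.0, lt=1.0)
    height_rho_per_year: float = Field(0.95, gt=0.0, lt=1.0)
    baseline_obesity_prevalence: float = Field(0.134, gt=0.0, lt=1.0)
    prevalence_age_slope: float = Field(0.062, ge=0.0)
    female_fraction: float = Field(0.48, ge=0.0, le=1.0)
    measurement_noise_sd_weight: float = Field(0.010, ge=0.0)
    measurement_noise_sd_height: float = Field(0.005, ge=0.0)
    unit_mix: UnitMix = Field(default_factory=UnitMix)
    error_rates: ErrorRates = Field(default_factory=ErrorRates)
    high_utilizer_rate: float = Field(0.0002, ge=0.0, le=1.0)
    high_utilizer_visits: tuple[int, int] = (101, 140)

    @model_validator(mode="after")
    def _ranges(self) -> "SyntheticConfig":
        lo, hi = self.first_age_range
        if not (0.0 < lo < hi):
            raise ValueError(f"invalid first_age_range {self.first_age_range}")
        if hi >= self.max_age_years:
            raise ValueError("first_age_range must lie below max_age_years")
        lo_v, hi_v = self.high_utilizer_visits
        if not (1 <= lo_v <= hi_v):
            raise ValueError(f"invalid high_utilizer_visits {self.high_utilizer_visits}")
        return self


@dataclass
class SyntheticCohort:
    """Generated visit table plus ground-truth side tables."""

    visits: pd.DataFrame
    truth: pd.DataFrame
    error_labels: pd.DataFrame
    config: SyntheticConfig

    def write(self, out_dir: Union[str, Path]) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.visits.to_csv(out_dir / "visits.csv", index=False)
        self.truth.to_csv(out_dir / "truth.csv", index=False)
        self.error_labels.to_csv(out_dir / "error_labels.csv", index=False)
        (out_dir / "config.json").write_text(self.config.model_dump_json(indent=2))


def _solve_latent_intercept(
    prevalence: float, slope: float, age_lo: float, age_hi: float, age_ref: float
) -> float:
    """Intercept of the latent BMIz mean so that first-exam obesity
    prevalence, averaged over the uniform first-age distribution, equals
    the configured value.  Obesity corresponds to latent z above the
    95th-percentile normal quantile."""
    zc = norm.ppf(0.95)
    grid = np.linspace(age_lo, age_hi, 201)

    def gap(mu0: float) -> float:
        return float(np.mean(norm.sf(zc - (mu0 + slope * (grid - age_ref))))) - prevalence

    return float(brentq(gap, -5.0, 5.0, xtol=1e-10))


def _ar1_path(
    visit_idx: np.ndarray, gaps_years: np.ndarray, rho: float, eps: np.ndarray
) -> np.ndarray:
    """Stationary standard-normal AR(1) sampled at irregular times.

    Rows must be ordered child-by-child with ``visit_idx`` counting visits
    within each child; the predecessor of a row is the row above it.
    """
    zeta = np.empty_like(gaps_years)
    first = visit_idx == 0
    zeta[first] = eps[first]
    phi = rho ** gaps_years
    innov = np.sqrt(1.0 - phi**2)
    for k in range(1, int(visit_idx.max()) + 1 if visit_idx.size else 0):
        sel = np.nonzero(visit_idx == k)[0]
        if sel.size == 0:
            break
        zeta[sel] = phi[sel] * zeta[sel - 1] + innov[sel] * eps[sel]
    return zeta


def _clip_to_domain(z: np.ndarray, L: np.ndarray, S: np.ndarray, margin: float = 0.05):
    """Clip z just inside the LMS inverse domain (1 + L*S*z > 0)."""
    with np.errstate(divide="ignore"):
        upper = np.where(L < 0, -1.0 / (L * S) - margin, np.inf)
        lower = np.where(L > 0, -1.0 / (L * S) + margin, -np.inf)
    return np.clip(z, lower, upper)


def generate_cohort(
    config: SyntheticConfig, reference: Optional[LMSReference] = None
) -> SyntheticCohort:
    """Generate a synthetic cohort; fully reproducible from ``config.seed``."""
    if reference is None:
        reference = synthetic_reference()
    rng = np.random.default_rng(config.seed)
    n = config.n_children

    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    n_visits = 1 + rng.poisson(config.visits_mean - 1.0, n)
    n_visits = np.clip(n_visits, 1, config.visits_max)
    hu = rng.random(n) < config.high_utilizer_rate
    lo_v, hi_v = config.high_utilizer_visits
    n_visits[hu] = rng.integers(lo_v, hi_v + 1, int(hu.sum()))

    age_lo, age_hi = config.first_age_range
    first_age = rng.uniform(age_lo, age_hi, n)
    birth_year = rng.integers(2000, 2013, n)

    total = int(n_visits.sum())
    child_row = np.repeat(np.arange(n), n_visits)
    first_pos = np.concatenate(([0], np.cumsum(n_visits)[:-1]))
    visit_idx = np.arange(total) - first_pos[child_row]

    # high utilizers are seen frequently: compress their gaps so 100+
    # visits fit inside the pediatric age range
    gap_scale = np.where(
        hu[child_row], 8.0 / n_visits[child_row], config.gap_mean_years
    )
    gaps = rng.exponential(1.0, total) * gap_scale
    gaps = np.maximum(gaps, 1.5 / 365.25)  # distinct calendar dates
    gaps[visit_idx == 0] = 0.0
    cs = np.cumsum(gaps)
    ages = first_age[child_row] + (cs - cs[first_pos][child_row])

    # drop the suffix of visits past the maximum age (ages increase per child)
    keep = ages <= config.max_age_years
    child_row = child_row[keep]
    ages = ages[keep]
    gaps = gaps[keep]
    total = ages.size
    first_mask = np.ones(total, dtype=bool)
    first_mask[1:] = child_row[1:] != child_row[:-1]
    visit_idx = np.arange(total) - np.maximum.accumulate(
        np.where(first_mask, np.arange(total), 0)
    )

    # latent BMIz: age-dependent mean plus stationary AR(1) noise
    age_ref = 0.5 * (age_lo + age_hi)
    mu0 = _solve_latent_intercept(
        config.baseline_obesity_prevalence,
        config.prevalence_age_slope,
        age_lo,
        age_hi,
        age_ref,
    )
    mu = mu0 + config.prevalence_age_slope * (ages - age_ref)
    zeta = _ar1_path(visit_idx, gaps, config.tracking_rho_per_year, rng.standard_normal(total))
    hz = _ar1_path(visit_idx, gaps, config.height_rho_per_year, rng.standard_normal(total))
    z = mu + zeta

    sex_row = sex[child_row]
    ages_months = ages * 12.0
    Lb, Mb, Sb = reference.params_mixed(sex_row, ages_months, "bmi")
    Lh, Mh, Sh = reference.params_mixed(sex_row, ages_months, "height")
    z_used = _clip_to_domain(z, Lb, Sb)
    hz_used = _clip_to_domain(hz, Lh, Sh)
    true_bmi = lms_inverse_arrays(z_used, Lb, Mb, Sb)
    true_height = lms_inverse_arrays(hz_used, Lh, Mh, Sh)
    true_weight = true_bmi * (true_height / 100.0) ** 2

    zc = norm.ppf(0.95)
    p95 = lms_inverse_arrays(zc, Lb, Mb, Sb)

    # benign measurement noise, applied before recording and error injection
    w_obs = true_weight * np.exp(
        config.measurement_noise_sd_weight * rng.standard_normal(total)
    )
    h_obs = true_height * np.exp(
        config.measurement_noise_sd_height * rng.standard_normal(total)
    )

    # unit system per child
    u = rng.random(n)
    mix = config.unit_mix
    system = np.where(
        u < mix.us_standard,
        "us",
        np.where(u < mix.us_standard + mix.metric, "metric", "mismatch"),
    )
    mismatch_kind = rng.random(n) < 0.5  # True: kg + in, False: lb + cm
    weight_unit_child = np.where(
        system == "us", "lb", np.where(system == "metric", "kg", np.where(mismatch_kind, "kg", "lb"))
    )
    height_unit_child = np.where(
        system == "us", "in", np.where(system == "metric", "cm", np.where(mismatch_kind, "in", "cm"))
    )
    weight_unit = weight_unit_child[child_row]
    height_unit = height_unit_child[child_row]
    weight_value = np.where(
        weight_unit == "lb", np.round(w_obs / LB_TO_KG, 1), np.round(w_obs, 2)
    )
    height_value = np.where(
        height_unit == "in", np.round(h_obs / IN_TO_CM, 1), np.round(h_obs, 1)
    )

    child_ids = np.array([f"C{i:07d}" for i in range(n)])
    birth_mid = pd.to_datetime(
        {"year": birth_year[child_row], "month": 7, "day": 1}
    )
    exam_date = birth_mid + pd.to_timedelta(np.round(ages * 365.25).astype(int), unit="D")

    visits = pd.DataFrame(
        {
            "record_id": np.arange(total),
            "child_id": child_ids[child_row],
            "sex": sex_row,
            "birth_year": birth_year[child_row],
            "exam_date": exam_date,
            "weight_value": weight_value,
            "weight_unit": weight_unit,
            "height_value": height_value,
            "height_unit": height_unit,
        }
    )

    truth = pd.DataFrame(
        {
            "record_id": np.arange(total),
            "child_id": child_ids[child_row],
            "exam_date": exam_date,
            "age_years": ages,
            "sex": sex_row,
            "true_weight_kg": true_weight,
            "true_height_cm": true_height,
            "true_bmi": true_bmi,
            "true_bmiz": z_used,
            "true_height_z": hz_used,
            "obese": true_bmi >= p95,
            "unit_system": system[child_row],
            "high_utilizer": hu[child_row],
        }
    )

    visits, labels = inject_errors(visits, config.error_rates, rng)
    return SyntheticCohort(visits=visits, truth=truth, error_labels=labels, config=config)


def _transpose_digits(value: float, selector: float, decimals: int) -> float:
    """Swap one adjacent digit pair of the printed value (transcription
    slip); falls back to a decimal shift when the swap is degenerate."""
    s = f"{value:.{decimals}f}"
    digits = [i for i, ch in enumerate(s) if ch.isdigit()]
    if len(digits) < 2:
        return value * 10.0
    j = int(selector * (len(digits) - 1))
    j = min(j, len(digits) - 2)
    a, b = digits[j], digits[j + 1]
    chars = list(s)
    chars[a], chars[b] = chars[b], chars[a]
    out = float("".join(chars))
    if out <= 0 or out == value:
        return value * 10.0
    return out


def inject_errors(
    visits: pd.DataFrame,
    error_rates: ErrorRates,
    rng: Union[int, np.random.Generator],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Corrupt a visit table in place (copy) and label every corruption.

    Each selected measurement receives exactly one error mode.
    Carried-forward values copy the *recorded* value of the child's
    previous row (which may itself already be corrupted, as in chained
    copy-forward).  Returns the corrupted table and a label table with
    columns ``record_id, child_id, exam_date, measure, error_mode,
    true_value`` (``true_value`` is the pre-corruption recorded value).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    df = visits.sort_values(["child_id", "exam_date"], kind="stable").reset_index(drop=True)
    n = len(df)
    child = df["child_id"].to_numpy()
    first = np.ones(n, dtype=bool)
    if n:
        first[1:] = child[1:] != child[:-1]

    uw = rng.random(n)
    uh = rng.random(n)
    ud = rng.random(n)
    t_coin = rng.random(n)  # decimal shift vs transposition
    t_dir = rng.random(n)  # shift direction
    t_pos_w = rng.random(n)
    t_pos_h = rng.random(n)
    dup_noise_w = rng.standard_normal(n)
    dup_noise_h = rng.standard_normal(n)

    er = error_rates
    w_mode = np.full(n, "", dtype=object)
    w_mode[uw < er.carried_forward_weight] = "carried_forward_weight"
    m = (uw >= er.carried_forward_weight) & (uw < er.carried_forward_weight + er.unit_swap)
    w_mode[m] = "unit_swap"
    m = (uw >= er.carried_forward_weight + er.unit_swap) & (
        uw < er.carried_forward_weight + er.unit_swap + er.transcription
    )
    w_mode[m] = "transcription"
    w_mode[first & (w_mode == "carried_forward_weight")] = ""

    h_mode = np.full(n, "", dtype=object)
    h_mode[uh < er.carried_forward_height] = "carried_forward_height"
    m = (uh >= er.carried_forward_height) & (uh < er.carried_forward_height + er.transcription)
    h_mode[m] = "transcription"
    h_mode[first & (h_mode == "carried_forward_height")] = ""

    wv = df["weight_value"].to_numpy(dtype=float).copy()
    hv = df["height_value"].to_numpy(dtype=float).copy()
    w_unit = df["weight_unit"].to_numpy()
    h_unit = df["height_unit"].to_numpy()
    rec_id = df["record_id"].to_numpy()
    dates = df["exam_date"].to_numpy()

    labels: list[tuple] = []

    def add_label(i: int, measure: str, mode: str, true_value: float) -> None:
        labels.append((rec_id[i], child[i], dates[i], measure, mode, true_value))

    for i in np.nonzero(w_mode != "")[0]:
        old = wv[i]
        mode = w_mode[i]
        if mode == "carried_forward_weight":
            wv[i] = wv[i - 1]
        elif mode == "unit_swap":
            if w_unit[i] == "kg":
                wv[i] = round(old / LB_TO_KG, 2)  # pound magnitude labeled kg
            else:
                wv[i] = round(old * LB_TO_KG, 1)  # kg magnitude labeled lb
            mode = "unit_swap"
        else:  # transcription
            if t_coin[i] < 0.5:
                wv[i] = old * 10.0 if t_dir[i] < 0.5 else old / 10.0
                mode = "decimal_shift"
            else:
                dec = 2 if w_unit[i] == "kg" else 1
                wv[i] = _transpose_digits(old, t_pos_w[i], dec)
                mode = "transposition"
        add_label(i, "weight", mode, old)

    for i in np.nonzero(h_mode != "")[0]:
        old = hv[i]
        mode = h_mode[i]
        if mode == "carried_forward_height":
            hv[i] = hv[i - 1]
        else:
            if t_coin[i] >= 0.5:  # decorrelate from the weight submode choice
                hv[i] = old * 10.0 if t_dir[i] < 0.5 else old / 10.0
                mode = "decimal_shift"
            else:
                hv[i] = _transpose_digits(old, t_pos_h[i], 1)
                mode = "transposition"
        add_label(i, "height", mode, old)

    df = df.copy()
    df["weight_value"] = wv
    df["height_value"] = hv

    dup_idx = np.nonzero(ud < er.same_day_duplicate)[0]
    if dup_idx.size:
        dups = df.iloc[dup_idx].copy()
        dups["record_id"] = np.arange(int(rec_id.max()) + 1, int(rec_id.max()) + 1 + dup_idx.size)
        dw = wv[dup_idx] * np.exp(0.1 * dup_noise_w[dup_idx])
        dh = hv[dup_idx] * np.exp(0.1 * dup_noise_h[dup_idx])
        dups["weight_value"] = np.where(
            dups["weight_unit"].to_numpy() == "kg", np.round(dw, 2), np.round(dw, 1)
        )
        dups["height_value"] = np.round(dh, 1)
        for j, i in enumerate(dup_idx):
            labels.append(
                (
                    int(dups["record_id"].iloc[j]),
                    child[i],
                    dates[i],
                    "record",
                    "same_day_duplicate",
                    np.nan,
                )
            )
        df = pd.concat([df, dups], ignore_index=True)
        df = df.sort_values(["child_id", "exam_date"], kind="stable").reset_index(drop=True)

    label_df = pd.DataFrame(labels, columns=LABEL_COLUMNS)
    return df, label_df
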