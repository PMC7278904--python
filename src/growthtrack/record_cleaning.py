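"""Longitudinal cleaning of EHR weight/height measurements.

Implements a measurement-quality pipeline for pediatric anthropometrics:

* unit conversion (lb -> kg, in -> cm) and exclusion of records with
  mismatched unit systems (a weight in kg next to a height in inches is
  usually a coding error rather than a real metric measurement);
* exclusion of children examined more than 100 times (extreme
  utilization suggests chronic illness and unrepresentative growth);
* resolution of several measurements on the same date, keeping the one
  most consistent with the child's other visits;
* carried-forward detection: weights identical to the previous
  examination are excluded; identical heights are excluded only when
  they follow a flagged height or persist for more than 3 months in
  children still growing (boys < 17 y, girls < 16 y) -- an unchanged
  height in an older adolescent can be real attained height;
* longitudinal outlier flagging: each measurement's modified z-score is
  compared with an expected value formed as an exponentially weighted
  moving average (EWMA) of the child's other visits, with weights
  ``(gap_days + 5) ** -1.5``; deviations beyond a threshold (default 3.5
  half-SD units) are excluded, worst first, re-computing after each
  exclusion so a gross error cannot shield itself by distorting its
  neighbours' expectations;
* a height decrease of more than 3 cm between examinations;
* extreme values (modified BMI z-score >= 25 or BMI >= 150 kg/m^2);
* a cohort-level screen for residual unit errors: each child's weights
  are smoothed against age with a robust local-linear scatterplot
  smoother, absolute residuals are pooled across the cohort, and a child
  is dropped when any residual is both above the pooled 99.95th
  percentile and more than 10 kg from the smoothed value.

The per-child detection stages run to a fixpoint, which makes the whole
pipeline idempotent: cleaning already-cleaned data excludes nothing.
Cleaning consumes only the visit table -- never synthetic truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import json
import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .cohort import estimate_ages
from .growth_reference import (
    IN_TO_CM,
    LB_TO_KG,
    LMSReference,
    modified_zscore_arrays,
    synthetic_reference,
)

__all__ = [
    "CleaningConfig",
    "FlagCode",
    "ChildTrajectory",
    "CleaningReport",
    "convert_and_screen_units",
    "exclude_high_utilizers",
    "ewma_expected",
    "detect_carried_forward",
    "flag_ewma_outliers",
    "flag_height_decrease",
    "resolve_same_day",
    "exclude_extreme",
    "smoother_screen",
    "clean",
    "retained_visits",
]


class FlagCode(str, Enum):
    UNIT_MISMATCH = "UNIT_MISMATCH"
    HIGH_UTILIZER = "HIGH_UTILIZER"
    SAME_DAY_DUPLICATE = "SAME_DAY_DUPLICATE"
    CARRIED_FORWARD_WEIGHT = "CARRIED_FORWARD_WEIGHT"
    CARRIED_FORWARD_HEIGHT = "CARRIED_FORWARD_HEIGHT"
    EWMA_OUTLIER_WEIGHT = "EWMA_OUTLIER_WEIGHT"
    EWMA_OUTLIER_HEIGHT = "EWMA_OUTLIER_HEIGHT"
    HEIGHT_DECREASE = "HEIGHT_DECREASE"
    EXTREME_BMI = "EXTREME_BMI"
    SMOOTHER_OUTLIER = "SMOOTHER_OUTLIER"


# order used to attribute an excluded record to a single primary cause
_PRIORITY = [
    FlagCode.UNIT_MISMATCH,
    FlagCode.HIGH_UTILIZER,
    FlagCode.SAME_DAY_DUPLICATE,
    FlagCode.CARRIED_FORWARD_WEIGHT,
    FlagCode.CARRIED_FORWARD_HEIGHT,
    FlagCode.EWMA_OUTLIER_WEIGHT,
    FlagCode.EWMA_OUTLIER_HEIGHT,
    FlagCode.HEIGHT_DECREASE,
    FlagCode.EXTREME_BMI,
    FlagCode.SMOOTHER_OUTLIER,
]

_HEIGHT_ERROR_CODES = {
    FlagCode.EWMA_OUTLIER_HEIGHT,
    FlagCode.HEIGHT_DECREASE,
    FlagCode.CARRIED_FORWARD_HEIGHT,
}

_SCHEMA = [
    "child_id",
    "sex",
    "birth_year",
    "exam_date",
    "weight_value",
    "weight_unit",
    "height_value",
    "height_unit",
]


@dataclass(frozen=True)
class CleaningConfig:
    """Tunable thresholds of the cleaning pipeline.

    Defaults follow the published rules; the EWMA kernel and threshold
    are configurable because different references tune them differently.
    """

    ewma_threshold: float = 3.5  # half-SD units of modified z
    ewma_offset_days: float = 5.0
    ewma_power: float = -1.5
    max_visits: int = 100  # children with MORE than this are dropped
    height_decrease_cm: float = 3.0
    cf_height_min_days: float = 3.0 * 365.25 / 12.0  # "more than 3 months"
    cf_height_age_limit_male: float = 17.0
    cf_height_age_limit_female: float = 16.0
    extreme_modified_bmiz: float = 25.0
    extreme_bmi: float = 150.0
    residual_quantile: float = 0.9995
    abs_kg: float = 10.0
    smoother_min_points: int = 5
    max_iterations: int = 10


@dataclass
class ChildTrajectory:
    """One child's date-ordered visits plus working exclusion masks."""

    child_id: str
    sex: str
    dates_days: np.ndarray  # days since epoch, sorted ascending
    ages_years: np.ndarray
    weight_kg: np.ndarray
    height_cm: np.ndarray
    bmi: np.ndarray
    mz_weight: np.ndarray
    mz_height: np.ndarray
    mz_bmi: np.ndarray
    row_index: np.ndarray  # positions in the cohort table
    rec_ok: np.ndarray = field(default=None)  # type: ignore[assignment]
    w_ok: np.ndarray = field(default=None)  # type: ignore[assignment]
    h_ok: np.ndarray = field(default=None)  # type: ignore[assignment]
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.dates_days)
        if self.rec_ok is None:
            self.rec_ok = np.ones(n, dtype=bool)
        if self.w_ok is None:
            self.w_ok = np.ones(n, dtype=bool)
        if self.h_ok is None:
            self.h_ok = np.ones(n, dtype=bool)
        if not self.flags:
            self.flags = [set() for _ in range(n)]
        if np.any(np.diff(self.dates_days) < 0):
            raise ValueError("trajectory visits must be date-sorted")

    def __len__(self) -> int:
        return len(self.dates_days)

    def flag(self, i: int, code: FlagCode) -> None:
        """Record a flag and exclude the record.

        The flag code names the offending measurement, but the whole
        record leaves the retained set: downstream analysis needs both
        measurements, and excluding at record scope keeps the pipeline
        idempotent (a second pass sees exactly the retained records the
        first pass's detection stages converged on).
        """
        self.flags[i].add(code)
        if code in (FlagCode.CARRIED_FORWARD_WEIGHT, FlagCode.EWMA_OUTLIER_WEIGHT):
            self.w_ok[i] = False
        elif code in _HEIGHT_ERROR_CODES:
            self.h_ok[i] = False
        self.rec_ok[i] = False

    def measure_ok(self, measure: str) -> np.ndarray:
        ok = self.w_ok if measure == "weight" else self.h_ok
        return ok & self.rec_ok


def _mz(traj: ChildTrajectory, measure: str) -> np.ndarray:
    return traj.mz_weight if measure == "weight" else traj.mz_height


def ewma_expected(
    traj: ChildTrajectory,
    index: int,
    measure: str,
    config: CleaningConfig = CleaningConfig(),
    exclude_date: bool = False,
) -> Optional[float]:
    """Expected modified z at one visit: time-weighted mean of the
    child's other retained visits, weight ``(gap_days + offset)**power``.

    Returns None when no other retained measurement exists (the caller
    must then skip EWMA flagging).  With ``exclude_date`` all visits
    sharing the index visit's date are left out (used when adjudicating
    same-day duplicates).
    """
    ok = traj.measure_ok(measure).copy()
    if exclude_date:
        ok &= traj.dates_days != traj.dates_days[index]
    else:
        ok[index] = False
    if not ok.any():
        return None
    gaps = np.abs(traj.dates_days[ok] - traj.dates_days[index]).astype(float)
    w = (gaps + config.ewma_offset_days) ** config.ewma_power
    v = _mz(traj, measure)[ok]
    return float(np.sum(w * v) / np.sum(w))


def resolve_same_day(traj: ChildTrajectory, config: CleaningConfig = CleaningConfig()) -> int:
    """Keep one row per date, preferring the row whose modified z-scores
    are closest to the EWMA expectation from the child's other dates;
    with no other dates to adjudicate, keep the first row in input
    order.  Returns the number of rows flagged."""
    n_flagged = 0
    dates = traj.dates_days
    i = 0
    while i < len(traj):
        j = i
        while j + 1 < len(traj) and dates[j + 1] == dates[i]:
            j += 1
        members = [k for k in range(i, j + 1) if traj.rec_ok[k]]
        if len(members) > 1:
            scores = []
            for k in members:
                score = 0.0
                n_terms = 0
                for measure in ("weight", "height"):
                    exp = ewma_expected(traj, k, measure, config, exclude_date=True)
                    if exp is not None:
                        score += abs(_mz(traj, measure)[k] - exp)
                        n_terms += 1
                scores.append(score if n_terms else np.inf)
            if np.all(np.isinf(scores)):
                keep = members[0]
            else:
                keep = members[int(np.argmin(scores))]
            for k in members:
                if k != keep:
                    traj.flag(k, FlagCode.SAME_DAY_DUPLICATE)
                    n_flagged += 1
        i = j + 1
    return n_flagged


def detect_carried_forward(
    traj: ChildTrajectory, config: CleaningConfig = CleaningConfig()
) -> int:
    """Flag carried-forward weights and heights.

    Weights: any retained weight exactly equal to the previous retained
    weight is excluded.  Heights: a height equal to the previous height
    is excluded only when it (a) follows a height flagged as a likely
    error, or (b) occurs in a still-growing child (boys < 17 y, girls
    < 16 y) and the value has persisted for more than 3 months; equal
    heights in older adolescents are kept as attained adult height.
    """
    n_flagged = 0
    prev = -1
    for j in range(len(traj)):
        if not (traj.rec_ok[j] and traj.w_ok[j]):
            continue
        if prev >= 0 and traj.weight_kg[j] == traj.weight_kg[prev]:
            traj.flag(j, FlagCode.CARRIED_FORWARD_WEIGHT)
            n_flagged += 1
            continue  # prev stays: chains of copies compare to the source
        prev = j

    age_limit = (
        config.cf_height_age_limit_female
        if traj.sex == "female"
        else config.cf_height_age_limit_male
    )
    # condition (a): the copy immediately follows a height already flagged
    # as a likely error (raw adjacency -- the flagged row itself is gone
    # from the retained set)
    for j in range(1, len(traj)):
        if not traj.rec_ok[j]:
            continue
        if traj.height_cm[j] == traj.height_cm[j - 1] and (
            traj.flags[j - 1] & _HEIGHT_ERROR_CODES
        ):
            traj.flag(j, FlagCode.CARRIED_FORWARD_HEIGHT)
            n_flagged += 1
    # condition (b): among retained visits, the value has persisted for
    # more than 3 months in a child still expected to be growing
    prev = -1
    run_start = -1
    for j in range(len(traj)):
        if not traj.rec_ok[j]:
            continue
        if prev >= 0 and traj.height_cm[j] == traj.height_cm[prev]:
            if run_start < 0:
                run_start = prev
            persisted = (
                traj.ages_years[j] < age_limit
                and (traj.dates_days[j] - traj.dates_days[run_start])
                > config.cf_height_min_days
            )
            if persisted:
                traj.flag(j, FlagCode.CARRIED_FORWARD_HEIGHT)
                n_flagged += 1
                continue  # run_start and prev keep pointing at the source
        else:
            run_start = -1
        prev = j
    return n_flagged


def flag_ewma_outliers(
    traj: ChildTrajectory,
    measure: str,
    config: CleaningConfig = CleaningConfig(),
) -> int:
    """Iteratively exclude the worst EWMA deviation above the threshold.

    Recomputes expectations after each exclusion.  Exact deviation ties
    (e.g. a two-visit child, where each visit deviates symmetrically from
    the other) are broken toward the value farther from the reference
    median.  Children with a single retained measurement are skipped.
    """
    values = _mz(traj, measure)
    code = (
        FlagCode.EWMA_OUTLIER_WEIGHT if measure == "weight" else FlagCode.EWMA_OUTLIER_HEIGHT
    )
    n_flagged = 0
    while True:
        idx = np.nonzero(traj.measure_ok(measure))[0]
        if idx.size < 2:
            break
        d = traj.dates_days[idx].astype(float)
        gaps = np.abs(d[:, None] - d[None, :])
        w = (gaps + config.ewma_offset_days) ** config.ewma_power
        np.fill_diagonal(w, 0.0)
        v = values[idx]
        expected = (w @ v) / w.sum(axis=1)
        dev = v - expected
        # tiny |value| term breaks exact ties toward the extreme value
        worst = int(np.argmax(np.abs(dev) + 1e-9 * np.abs(v)))
        if np.abs(dev[worst]) > config.ewma_threshold:
            traj.flag(int(idx[worst]), code)
            n_flagged += 1
        else:
            break
    return n_flagged


def flag_height_decrease(
    traj: ChildTrajectory, config: CleaningConfig = CleaningConfig()
) -> int:
    """Flag heights more than 3 cm below the previous retained height."""
    n_flagged = 0
    prev = -1
    for j in range(len(traj)):
        if not (traj.rec_ok[j] and traj.h_ok[j]):
            continue
        if prev >= 0 and traj.height_cm[j] < traj.height_cm[prev] - config.height_decrease_cm:
            traj.flag(j, FlagCode.HEIGHT_DECREASE)
            n_flagged += 1
            continue
        prev = j
    return n_flagged


def exclude_extreme(traj: ChildTrajectory, config: CleaningConfig = CleaningConfig()) -> int:
    """Exclude records with modified BMI z >= 25 or BMI >= 150 kg/m^2."""
    n_flagged = 0
    for j in range(len(traj)):
        if not (traj.rec_ok[j] and traj.w_ok[j] and traj.h_ok[j]):
            continue
        if (
            traj.mz_bmi[j] >= config.extreme_modified_bmiz
            or traj.bmi[j] >= config.extreme_bmi
        ):
            traj.flag(j, FlagCode.EXTREME_BMI)
            n_flagged += 1
    return n_flagged


def smoother_screen(
    trajectories: list[ChildTrajectory],
    config: CleaningConfig = CleaningConfig(),
) -> list[str]:
    """Cohort-level residual screen for remaining unit-scale weight errors.

    Each child's retained weights are smoothed against age with a robust
    local-linear scatterplot smoother; absolute residuals are pooled
    across the cohort, and a child is excluded when any residual exceeds
    both the pooled ``residual_quantile`` and ``abs_kg``.  Children with
    fewer than ``smoother_min_points`` retained weights skip the screen.
    Returns the flagged child ids (rows are flagged in place).
    """
    residuals: list[np.ndarray] = []
    owners: list[ChildTrajectory] = []
    for traj in trajectories:
        ok = traj.w_ok & traj.rec_ok
        if int(ok.sum()) < config.smoother_min_points:
            continue
        x = traj.ages_years[ok]
        y = traj.weight_kg[ok]
        frac = min(1.0, max(0.5, config.smoother_min_points / ok.sum()))
        smooth = lowess(y, x, frac=frac, it=2, return_sorted=False)
        residuals.append(np.abs(y - smooth))
        owners.append(traj)
    if not residuals:
        return []
    # the pooled quantile is re-evaluated after each round of exclusions
    # (a flagged child's residuals leave the pool) until stable, so a
    # second cleaning pass finds nothing new
    in_pool = np.ones(len(owners), dtype=bool)
    while True:
        pooled = np.concatenate([r for r, keep in zip(residuals, in_pool) if keep])
        q = float(np.quantile(pooled, config.residual_quantile))
        newly = [
            i
            for i in np.nonzero(in_pool)[0]
            if np.any((residuals[i] > q) & (residuals[i] > config.abs_kg))
        ]
        if not newly:
            break
        in_pool[newly] = False
    flagged: list[str] = []
    for i in np.nonzero(~in_pool)[0]:
        traj = owners[i]
        for j in range(len(traj)):
            if traj.rec_ok[j]:
                traj.flag(j, FlagCode.SMOOTHER_OUTLIER)
        flagged.append(traj.child_id)
    return flagged


@dataclass
class CleaningReport:
    """Per-stage accounting of the cleaning pipeline."""

    records_in: int
    records_out: int
    children_in: int
    children_out: int
    flag_counts: dict  # code -> number of rows carrying the flag
    excluded_records_by_code: dict  # primary-cause attribution, sums to exclusions

    def __post_init__(self) -> None:
        excluded = self.records_in - self.records_out
        total_attributed = sum(self.excluded_records_by_code.values())
        if total_attributed != excluded:
            raise ValueError(
                f"attribution mismatch: {total_attributed} attributed vs "
                f"{excluded} excluded"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "flag": code.value,
                "rows_flagged": self.flag_counts.get(code, 0),
                "records_excluded": self.excluded_records_by_code.get(code, 0),
            }
            for code in _PRIORITY
        ]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "records_in": self.records_in,
                "records_out": self.records_out,
                "children_in": self.children_in,
                "children_out": self.children_out,
                "flag_counts": {c.value: int(v) for c, v in self.flag_counts.items()},
                "excluded_records_by_code": {
                    c.value: int(v) for c, v in self.excluded_records_by_code.items()
                },
            },
            indent=2,
        )


def convert_and_screen_units(visits: pd.DataFrame) -> pd.DataFrame:
    """Convert recorded values to metric and flag mixed-unit records.

    Adds ``weight_kg``, ``height_cm`` and boolean ``unit_mismatch``
    columns.  A record is mismatched when one measure is US-standard and
    the other metric.  Unknown unit codes are rejected.
    """
    df = visits.copy()
    wu = df["weight_unit"].to_numpy()
    hu = df["height_unit"].to_numpy()
    bad = set(np.unique(wu)) - {"lb", "kg"} | (set(np.unique(hu)) - {"in", "cm"})
    if bad:
        raise ValueError(f"unknown unit codes: {sorted(bad)}")
    w = df["weight_value"].to_numpy(dtype=float)
    h = df["height_value"].to_numpy(dtype=float)
    df["weight_kg"] = np.where(wu == "lb", w * LB_TO_KG, w)
    df["height_cm"] = np.where(hu == "in", h * IN_TO_CM, h)
    df["unit_mismatch"] = (wu == "lb") != (hu == "in")
    return df


def exclude_high_utilizers(
    visits: pd.DataFrame, max_visits: int = 100
) -> tuple[pd.DataFrame, list[str]]:
    """Drop children examined more than ``max_visits`` times (child scope)."""
    counts = visits.groupby("child_id").size()
    flagged = counts.index[counts > max_visits].tolist()
    return visits[~visits["child_id"].isin(flagged)].copy(), flagged


def _empty_report() -> CleaningReport:
    return CleaningReport(0, 0, 0, 0, {}, {})


def clean(
    visits: pd.DataFrame,
    reference: Optional[LMSReference] = None,
    config: Optional[CleaningConfig] = None,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Run the full cleaning pipeline on a visit table.

    Returns the input table (all rows, original order restored) with
    added columns ``weight_kg, height_cm, age_years, bmi, mod_z_weight,
    mod_z_height, mod_z_bmi, flag_codes, weight_retained,
    height_retained, retained`` plus a :class:`CleaningReport`.  A record
    is retained when neither of its measurements nor the record itself is
    flagged.
    """
    if reference is None:
        reference = synthetic_reference()
    if config is None:
        config = CleaningConfig()
    missing = set(_SCHEMA) - set(visits.columns)
    if missing:
        raise ValueError(f"visit table missing columns: {sorted(missing)}")
    if visits.empty:
        out = visits.copy()
        for col in (
            "weight_kg",
            "height_cm",
            "age_years",
            "bmi",
            "mod_z_weight",
            "mod_z_height",
            "mod_z_bmi",
        ):
            out[col] = np.nan
        out["flag_codes"] = ""
        out["weight_retained"] = out["height_retained"] = out["retained"] = np.array(
            [], dtype=bool
        )
        return out, _empty_report()

    df = visits.copy()
    df["exam_date"] = pd.to_datetime(df["exam_date"])
    df["_input_order"] = np.arange(len(df))
    df = df.sort_values(["child_id", "exam_date", "_input_order"], kind="stable")
    df = df.reset_index(drop=True)
    df = convert_and_screen_units(df)
    df["age_years"] = estimate_ages(df["exam_date"], df["birth_year"])
    if (df["age_years"] < 0).any():
        bad = df.loc[df["age_years"] < 0, "child_id"].unique()[:5]
        raise ValueError(f"examination before midpoint of birth year for {list(bad)}")

    n = len(df)
    flags: list[set] = [set() for _ in range(n)]
    mismatch = df["unit_mismatch"].to_numpy()
    for i in np.nonzero(mismatch)[0]:
        flags[i].add(FlagCode.UNIT_MISMATCH)

    counts = df.groupby("child_id")["child_id"].transform("size")
    high_util = (counts > config.max_visits).to_numpy()
    for i in np.nonzero(high_util)[0]:
        flags[i].add(FlagCode.HIGH_UTILIZER)

    active = ~mismatch & ~high_util
    sex_arr = df["sex"].to_numpy()
    ages = df["age_years"].to_numpy()
    wkg = df["weight_kg"].to_numpy()
    hcm = df["height_cm"].to_numpy()
    bmi_arr = wkg / (hcm / 100.0) ** 2
    mzw = np.full(n, np.nan)
    mzh = np.full(n, np.nan)
    mzb = np.full(n, np.nan)
    if active.any():
        months = ages[active] * 12.0
        L, M, S = reference.params_mixed(sex_arr[active], months, "weight")
        mzw[active] = modified_zscore_arrays(wkg[active], L, M, S)
        L, M, S = reference.params_mixed(sex_arr[active], months, "height")
        mzh[active] = modified_zscore_arrays(hcm[active], L, M, S)
        L, M, S = reference.params_mixed(sex_arr[active], months, "bmi")
        mzb[active] = modified_zscore_arrays(bmi_arr[active], L, M, S)

    dates_days = (
        df["exam_date"].to_numpy().astype("datetime64[D]").astype(np.int64)
    )
    child_arr = df["child_id"].to_numpy()

    # child block boundaries (table is sorted by child)
    boundaries = np.nonzero(
        np.concatenate(([True], child_arr[1:] != child_arr[:-1]))
    )[0]
    boundaries = np.append(boundaries, n)

    trajectories: list[ChildTrajectory] = []
    for b, e in zip(boundaries[:-1], boundaries[1:]):
        rows = np.arange(b, e)
        act = active[rows]
        if not act.any():
            continue
        rows = rows[act]
        traj = ChildTrajectory(
            child_id=str(child_arr[rows[0]]),
            sex=str(sex_arr[rows[0]]),
            dates_days=dates_days[rows],
            ages_years=ages[rows],
            weight_kg=wkg[rows],
            height_cm=hcm[rows],
            bmi=bmi_arr[rows],
            mz_weight=mzw[rows],
            mz_height=mzh[rows],
            mz_bmi=mzb[rows],
            row_index=rows,
        )
        resolve_same_day(traj, config)
        for _ in range(config.max_iterations):
            changed = 0
            changed += detect_carried_forward(traj, config)
            changed += flag_ewma_outliers(traj, "weight", config)
            changed += flag_ewma_outliers(traj, "height", config)
            changed += flag_height_decrease(traj, config)
            changed += exclude_extreme(traj, config)
            if changed == 0:
                break
        trajectories.append(traj)

    smoother_screen(trajectories, config)

    w_ret = ~mismatch & ~high_util
    h_ret = w_ret.copy()
    rec_row_ok = w_ret.copy()
    for traj in trajectories:
        w_ret[traj.row_index] = traj.w_ok
        h_ret[traj.row_index] = traj.h_ok
        rec_row_ok[traj.row_index] = traj.rec_ok
        for local, row in enumerate(traj.row_index):
            flags[row] |= traj.flags[local]
    retained = w_ret & h_ret & rec_row_ok

    flag_counts: dict = {}
    primary: dict = {}
    for i in range(n):
        for code in flags[i]:
            flag_counts[code] = flag_counts.get(code, 0) + 1
        if not retained[i]:
            first = min(flags[i], key=_PRIORITY.index)
            primary[first] = primary.get(first, 0) + 1

    df["mod_z_weight"] = mzw
    df["mod_z_height"] = mzh
    df["mod_z_bmi"] = mzb
    df["bmi"] = bmi_arr
    df["flag_codes"] = [
        ";".join(sorted(c.value for c in s)) for s in flags
    ]
    df["weight_retained"] = w_ret & rec_row_ok
    df["height_retained"] = h_ret & rec_row_ok
    df["retained"] = retained

    report = CleaningReport(
        records_in=n,
        records_out=int(retained.sum()),
        children_in=int(pd.unique(child_arr).size),
        children_out=int(pd.unique(child_arr[retained]).size),
        flag_counts=flag_counts,
        excluded_records_by_code=primary,
    )
    df = df.sort_values("_input_order").drop(columns=["_input_order", "unit_mismatch"])
    return df.reset_index(drop=True), report


def retained_visits(cleaned: pd.DataFrame) -> pd.DataFrame:
    """Schema-shaped table of fully retained records, in metric units
    (suitable for re-cleaning or downstream cohort construction)."""
    out = cleaned.loc[cleaned["retained"], _SCHEMA].copy()
    out["weight_value"] = cleaned.loc[cleaned["retained"], "weight_kg"].to_numpy()
    out["weight_unit"] = "kg"
    out["height_value"] = cleaned.loc[cleaned["retained"], "height_cm"].to_numpy()
    out["height_unit"] = "cm"
    if "record_id" in cleaned.columns:
        out.insert(0, "record_id", cleaned.loc[cleaned["retained"], "record_id"].to_numpy())
    return out.reset_index(drop=True)
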