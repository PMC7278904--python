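import numpy as np
import pandas as pd
import pytest
from conftest import visits_frame

from growthtrack import (
    CleaningConfig,
    ErrorRates,
    FlagCode,
    SyntheticConfig,
    UnitMix,
    clean,
    convert_and_screen_units,
    generate_cohort,
    retained_visits,
)
from growthtrack.record_cleaning import (
    ChildTrajectory,
    detect_carried_forward,
    ewma_expected,
    exclude_extreme,
    exclude_high_utilizers,
    flag_ewma_outliers,
    flag_height_decrease,
    resolve_same_day,
    smoother_screen,
)

CFG = CleaningConfig()


def make_traj(
    dates_days,
    weights=None,
    heights=None,
    mzw=None,
    mzh=None,
    mzb=None,
    bmi=None,
    ages=None,
    sex="male",
):
    n = len(dates_days)
    dates = np.asarray(dates_days, dtype=np.int64)
    # default weights/heights vary so they never trip the
    # carried-forward rules by accident
    return ChildTrajectory(
        child_id="T",
        sex=sex,
        dates_days=dates,
        ages_years=np.asarray(ages if ages is not None else dates / 365.25, dtype=float),
        weight_kg=np.asarray(
            weights if weights is not None else 20.0 + 0.5 * np.arange(n), dtype=float
        ),
        height_cm=np.asarray(
            heights if heights is not None else 110.0 + 2.0 * np.arange(n), dtype=float
        ),
        bmi=np.asarray(bmi if bmi is not None else np.full(n, 16.5), dtype=float),
        mz_weight=np.asarray(mzw if mzw is not None else np.zeros(n), dtype=float),
        mz_height=np.asarray(mzh if mzh is not None else np.zeros(n), dtype=float),
        mz_bmi=np.asarray(mzb if mzb is not None else np.zeros(n), dtype=float),
        row_index=np.arange(n),
    )


# ---------------------------------------------------------------------------
# unit handling
# ---------------------------------------------------------------------------


def test_unit_conversion_and_mismatch():
    df = visits_frame(
        [
            ("A", "male", 2005, "2010-01-01", 100.0, "lb", 60.0, "in"),
            ("B", "male", 2005, "2010-01-01", 30.0, "kg", 120.0, "cm"),
            ("C", "male", 2005, "2010-01-01", 30.0, "kg", 47.0, "in"),
        ]
    )
    out = convert_and_screen_units(df)
    assert out["weight_kg"].iloc[0] == pytest.approx(45.359237)
    assert out["height_cm"].iloc[0] == pytest.approx(152.4)
    assert out["weight_kg"].iloc[1] == 30.0 and out["height_cm"].iloc[1] == 120.0
    assert out["unit_mismatch"].tolist() == [False, False, True]


def test_unknown_unit_code_rejected():
    df = visits_frame([("A", "male", 2005, "2010-01-01", 30.0, "stone", 120.0, "cm")])
    with pytest.raises(ValueError, match="unit"):
        convert_and_screen_units(df)


def test_high_utilizer_boundary():
    """More than 100 visits excludes the child; exactly 100 is retained."""
    rows = []
    for i in range(101):
        rows.append(("A", "male", 2005, pd.Timestamp("2008-01-01") + pd.Timedelta(days=30 * i), 30.0, "kg", 120.0, "cm"))
    for i in range(100):
        rows.append(("B", "male", 2005, pd.Timestamp("2008-01-01") + pd.Timedelta(days=30 * i), 30.0, "kg", 120.0, "cm"))
    df = visits_frame(rows)
    kept, flagged = exclude_high_utilizers(df, max_visits=100)
    assert flagged == ["A"]
    assert set(kept["child_id"]) == {"B"}
    empty, none_flagged = exclude_high_utilizers(df.iloc[0:0])
    assert empty.empty and none_flagged == []


# ---------------------------------------------------------------------------
# carried forward
# ---------------------------------------------------------------------------


def test_carried_forward_weight_exact_equality():
    traj = make_traj([0, 182], weights=[12.0, 12.0])
    assert detect_carried_forward(traj, CFG) == 1
    assert FlagCode.CARRIED_FORWARD_WEIGHT in traj.flags[1]
    assert traj.flags[0] == set()


def test_carried_forward_weight_chain_compares_to_source():
    traj = make_traj([0, 100, 200], weights=[12.0, 12.0, 12.0])
    detect_carried_forward(traj, CFG)
    assert FlagCode.CARRIED_FORWARD_WEIGHT in traj.flags[1]
    assert FlagCode.CARRIED_FORWARD_WEIGHT in traj.flags[2]


def test_carried_forward_height_young_and_persistent():
    # equal heights at ages 5.0 and 5.4 y (~5 months apart) in a boy
    traj = make_traj(
        [int(5.0 * 365.25), int(5.4 * 365.25)],
        heights=[110.0, 110.0],
        ages=[5.0, 5.4],
    )
    detect_carried_forward(traj, CFG)
    assert FlagCode.CARRIED_FORWARD_HEIGHT in traj.flags[1]


def test_carried_forward_height_short_gap_retained():
    traj = make_traj(
        [int(5.0 * 365.25), int(5.0 * 365.25) + 60],
        heights=[110.0, 110.0],
        ages=[5.0, 5.16],
    )
    assert detect_carried_forward(traj, CFG) == 0


def test_carried_forward_height_older_boy_retained():
    """An unchanged height after a boy turns 17 is attained height."""
    traj = make_traj(
        [int(17.2 * 365.25), int(17.8 * 365.25)],
        heights=[176.0, 176.0],
        ages=[17.2, 17.8],
    )
    assert detect_carried_forward(traj, CFG) == 0


def test_carried_forward_height_after_flagged_height():
    """A height equal to an immediately preceding flagged height is
    excluded regardless of the time gap (condition a)."""
    traj = make_traj(
        [0, 30, 60],
        heights=[110.0, 140.0, 140.0],
        ages=[5.0, 5.08, 5.16],
    )
    traj.flag(1, FlagCode.EWMA_OUTLIER_HEIGHT)
    detect_carried_forward(traj, CFG)
    assert FlagCode.CARRIED_FORWARD_HEIGHT in traj.flags[2]


# ---------------------------------------------------------------------------
# EWMA
# ---------------------------------------------------------------------------


def test_ewma_expected_single_other_visit():
    traj = make_traj([0, 200], mzw=[1.2, 0.0])
    assert ewma_expected(traj, 1, "weight", CFG) == pytest.approx(1.2)


def test_ewma_expected_symmetric_neighbors():
    traj = make_traj([0, 100, 200], mzw=[0.0, 5.0, 2.0])
    assert ewma_expected(traj, 1, "weight", CFG) == pytest.approx(1.0)


def test_ewma_expected_matches_bruteforce():
    rng = np.random.default_rng(12)
    dates = np.sort(rng.integers(0, 2000, 6))
    mz = rng.normal(0, 1, 6)
    traj = make_traj(dates, mzw=mz)
    for i in range(6):
        gaps = np.abs(dates - dates[i]).astype(float)
        w = (gaps + 5.0) ** -1.5
        w[i] = 0.0
        expected = np.sum(w * mz) / np.sum(w)
        assert ewma_expected(traj, i, "weight", CFG) == pytest.approx(expected)


def test_ewma_expected_undefined_for_singleton():
    traj = make_traj([0], mzw=[1.0])
    assert ewma_expected(traj, 0, "weight", CFG) is None


def test_ewma_outlier_spike_flagged():
    traj = make_traj([0, 180, 360, 540], mzw=[0.0, 0.0, 8.0, 0.0])
    assert flag_ewma_outliers(traj, "weight", CFG) == 1
    assert FlagCode.EWMA_OUTLIER_WEIGHT in traj.flags[2]


def test_ewma_no_flags_when_within_threshold():
    traj = make_traj([0, 180, 360], mzw=[0.5, -0.5, 0.4])
    assert flag_ewma_outliers(traj, "weight", CFG) == 0
    constant = make_traj([0, 180, 360], mzh=[1.0, 1.0, 1.0])
    assert flag_ewma_outliers(constant, "height", CFG) == 0


def test_ewma_two_visit_tie_flags_extreme_value():
    traj = make_traj([0, 200], mzw=[0.1, 9.0])
    flag_ewma_outliers(traj, "weight", CFG)
    assert FlagCode.EWMA_OUTLIER_WEIGHT in traj.flags[1]
    assert traj.flags[0] == set()


# ---------------------------------------------------------------------------
# height decrease / same day / extremes
# ---------------------------------------------------------------------------


def test_height_decrease_rule():
    traj = make_traj([0, 200], heights=[110.0, 106.5])
    assert flag_height_decrease(traj, CFG) == 1
    assert FlagCode.HEIGHT_DECREASE in traj.flags[1]
    ok = make_traj([0, 200], heights=[110.0, 107.5])
    assert flag_height_decrease(ok, CFG) == 0
    mono = make_traj([0, 200, 400], heights=[110.0, 113.0, 118.0])
    assert flag_height_decrease(mono, CFG) == 0


def test_same_day_keeps_value_closest_to_expectation():
    traj = make_traj([0, 300, 300], mzw=[0.0, 0.1, 5.0], mzh=[0.0, 0.0, 0.0])
    resolve_same_day(traj, CFG)
    assert traj.rec_ok[1]
    assert FlagCode.SAME_DAY_DUPLICATE in traj.flags[2]


def test_same_day_three_duplicates():
    traj = make_traj(
        [0, 300, 300, 300],
        mzw=[1.0, 0.8, 1.1, 3.0],
        mzh=[1.0, 0.8, 1.1, 3.0],
    )
    resolve_same_day(traj, CFG)
    assert traj.rec_ok[2]
    assert not traj.rec_ok[1] and not traj.rec_ok[3]


def test_same_day_without_other_dates_keeps_first():
    traj = make_traj([100, 100], mzw=[2.0, 0.0])
    resolve_same_day(traj, CFG)
    assert traj.rec_ok[0] and not traj.rec_ok[1]


@pytest.mark.parametrize(
    "bmi_value, mzb, excluded",
    [
        (150.0, 0.0, True),  # inclusive boundary
        (149.9, 24.0, False),
        (30.0, 25.0, True),  # inclusive boundary
        (30.0, 24.9, False),
    ],
)
def test_extreme_rule_boundaries(bmi_value, mzb, excluded):
    traj = make_traj([0], bmi=[bmi_value], mzb=[mzb])
    exclude_extreme(traj, CFG)
    assert (FlagCode.EXTREME_BMI in traj.flags[0]) is excluded


# ---------------------------------------------------------------------------
# smoother screen
# ---------------------------------------------------------------------------


def test_smoother_screen_flags_injected_spike():
    """One +50 kg single-visit spike in a smooth cohort is the only
    child excluded; smooth children and sub-10kg deviations survive."""
    rng = np.random.default_rng(0)
    trajs = []
    for c in range(400):
        ages = np.sort(rng.uniform(3, 12, 8))
        w = 10.0 + 3.0 * ages + rng.normal(0, 0.5, 8)
        if c == 0:
            w[4] += 50.0
        t = make_traj((ages * 365.25).astype(int), weights=w, ages=ages)
        t.child_id = f"C{c}"
        trajs.append(t)
    flagged = smoother_screen(trajs, CFG)
    assert flagged == ["C0"]
    assert not trajs[1].flags[0]


def test_smoother_requires_both_conditions():
    """A residual above the pooled quantile but under 10 kg is kept."""
    rng = np.random.default_rng(1)
    trajs = []
    for c in range(200):
        ages = np.sort(rng.uniform(3, 12, 8))
        w = 10.0 + 3.0 * ages + rng.normal(0, 0.5, 8)
        if c == 0:
            w[4] += 8.0  # large but below the absolute threshold
        t = make_traj((ages * 365.25).astype(int), weights=w, ages=ages)
        t.child_id = f"C{c}"
        trajs.append(t)
    assert smoother_screen(trajs, CFG) == []


def test_smoother_skips_short_trajectories():
    t = make_traj([0, 300, 600], weights=[20.0, 90.0, 21.0])
    assert smoother_screen([t], CFG) == []


# ---------------------------------------------------------------------------
# end-to-end clean
# ---------------------------------------------------------------------------


def test_clean_empty_input(reference):
    out, report = clean(visits_frame([]), reference)
    assert out.empty
    assert report.records_in == report.records_out == 0
    assert report.flag_counts == {}


def test_clean_error_free_cohort_retains_nearly_everything(
    clean_metric_config, reference
):
    """With no injected errors, the per-measurement rules exclude under
    1% of records.  The cohort-level smoother screen additionally drops
    a small number of whole children whose (legitimate) weight swings in
    the far LMS tail exceed 10 kg from their smoothed curve, so overall
    retention is slightly lower; that screen trades a little specificity
    for catching residual unit-scale errors."""
    coh = generate_cohort(clean_metric_config)
    cleaned, report = clean(coh.visits, reference)
    assert report.records_in == len(coh.visits)
    not_smoother = ~cleaned["flag_codes"].str.contains("SMOOTHER_OUTLIER")
    measurement_rule_retention = (cleaned["retained"] | ~not_smoother).mean()
    assert measurement_rule_retention >= 0.99
    assert report.records_out / report.records_in >= 0.97


def test_clean_accounting_invariant(small_corrupted_cohort, reference):
    """Primary-cause exclusion counts sum exactly to records_in -
    records_out, and every excluded row carries at least one flag."""
    cleaned, report = clean(small_corrupted_cohort.visits, reference)
    assert sum(report.excluded_records_by_code.values()) == (
        report.records_in - report.records_out
    )
    excluded = cleaned[~cleaned["retained"]]
    assert (excluded["flag_codes"] != "").all()
    retained = cleaned[cleaned["retained"]]
    assert (retained["flag_codes"] == "").all()
    assert report.children_out <= report.children_in


def test_clean_is_blind_to_truth_columns(small_corrupted_cohort, reference):
    """Cleaning consumes only the visit schema -- adding or removing
    side-channel columns does not change the result."""
    visits = small_corrupted_cohort.visits
    with_extra = visits.copy()
    with_extra["true_hint"] = 1.0
    a, _ = clean(visits, reference)
    b, _ = clean(with_extra, reference)
    pd.testing.assert_series_equal(a["retained"], b["retained"])


def test_clean_idempotent_on_small_cohort(small_corrupted_cohort, reference):
    cleaned, _ = clean(small_corrupted_cohort.visits, reference)
    second, report2 = clean(retained_visits(cleaned), reference)
    assert report2.records_in == report2.records_out
    assert (second["retained"]).all()


def test_clean_preserves_row_order_and_count(small_corrupted_cohort, reference):
    cleaned, _ = clean(small_corrupted_cohort.visits, reference)
    assert len(cleaned) == len(small_corrupted_cohort.visits)
    assert cleaned["record_id"].tolist() == small_corrupted_cohort.visits[
        "record_id"
    ].tolist()


def test_clean_rejects_exam_before_birth(reference):
    df = visits_frame([("A", "male", 2005, "2005-06-30", 12.0, "kg", 85.0, "cm")])
    with pytest.raises(ValueError, match="birth"):
        clean(df, reference)
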