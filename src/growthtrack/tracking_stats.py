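"""Obesity-tracking statistics.

Treats obesity at the first examination as a screening "test" for
obesity at the last examination and summarizes their 2x2
cross-classification with the relative risk (RR), sensitivity,
specificity and positive predictive value (PPV), each with a 95%
confidence interval.  With the table

    a = obese first & obese last        b = obese first & not last
    c = not first & obese last          d = not first & not last

the statistics are RR = [a/(a+b)] / [c/(c+d)], sensitivity = a/(a+c),
specificity = d/(b+d), PPV = a/(a+b).  Proportion intervals use the
Wald normal approximation; the RR interval is the Katz log-normal
interval exp(ln RR +/- z * sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))).

Also provided: stratification by initial age and follow-up interval,
persistence patterns across three age windows, grouped prevalence, and
the prevalence-ratio upper bound on sensitivity (when prevalence rises
with age, the sensitivity of early obesity for later obesity can be no
larger than the ratio of the two prevalences).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "CrossTab2x2",
    "EstimateCI",
    "TrackingStatistics",
    "crosstab",
    "relative_risk",
    "screening_stats",
    "stratified_tracking",
    "persistence_patterns",
    "prevalence",
    "max_sensitivity_bound",
    "DEFAULT_INTERVAL_BINS",
]

DEFAULT_INTERVAL_BINS = (1.0, 2.0, 5.0, 8.0, np.inf)


@dataclass(frozen=True)
class CrossTab2x2:
    """Counts of obesity at the first (rows) by last (columns) exam."""

    a: int  # obese first, obese last
    b: int  # obese first, not obese last
    c: int  # not obese first, obese last
    d: int  # not obese first, not obese last

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def __add__(self, other: "CrossTab2x2") -> "CrossTab2x2":
        return CrossTab2x2(
            self.a + other.a, self.b + other.b, self.c + other.c, self.d + other.d
        )


@dataclass(frozen=True)
class EstimateCI:
    estimate: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.estimate <= self.upper):
            raise ValueError(
                f"interval ({self.lower}, {self.upper}) does not contain {self.estimate}"
            )


@dataclass(frozen=True)
class TrackingStatistics:
    """Screening statistics in percent (RR unitless), with 95% CIs.

    A statistic whose margin is empty is ``None`` rather than a number.
    """

    rr: Optional[EstimateCI]
    sensitivity: Optional[EstimateCI]
    specificity: Optional[EstimateCI]
    ppv: Optional[EstimateCI]
    n: int


def crosstab(first_obese, last_obese=None) -> CrossTab2x2:
    """Tally first-by-last obesity status.

    Accepts either a pair DataFrame with ``first_obese`` / ``last_obese``
    columns or two boolean arrays.
    """
    if last_obese is None:
        first = np.asarray(first_obese["first_obese"], dtype=bool)
        last = np.asarray(first_obese["last_obese"], dtype=bool)
    else:
        first = np.asarray(first_obese, dtype=bool)
        last = np.asarray(last_obese, dtype=bool)
    if first.shape != last.shape:
        raise ValueError("status arrays must have equal length")
    return CrossTab2x2(
        a=int(np.sum(first & last)),
        b=int(np.sum(first & ~last)),
        c=int(np.sum(~first & last)),
        d=int(np.sum(~first & ~last)),
    )


def _wald_percent(k: int, n: int, alpha: float) -> EstimateCI:
    p = k / n
    z = norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(p * (1.0 - p) / n)
    return EstimateCI(
        estimate=100.0 * p,
        lower=max(0.0, 100.0 * (p - half)),
        upper=min(100.0, 100.0 * (p + half)),
    )


def relative_risk(ct: CrossTab2x2, alpha: float = 0.05) -> EstimateCI:
    """RR with the Katz log-normal interval (no continuity correction)."""
    if ct.a + ct.b == 0 or ct.c + ct.d == 0:
        raise ValueError("relative risk undefined: an exposure margin is empty")
    if ct.c == 0:
        raise ValueError("relative risk undefined: zero risk in the unexposed row")
    if ct.a == 0:
        raise ValueError("log-normal RR interval undefined with a = 0")
    risk1 = ct.a / (ct.a + ct.b)
    risk0 = ct.c / (ct.c + ct.d)
    rr = risk1 / risk0
    z = norm.ppf(1.0 - alpha / 2.0)
    se = np.sqrt(1.0 / ct.a - 1.0 / (ct.a + ct.b) + 1.0 / ct.c - 1.0 / (ct.c + ct.d))
    return EstimateCI(
        estimate=rr,
        lower=float(rr * np.exp(-z * se)),
        upper=float(rr * np.exp(z * se)),
    )


def screening_stats(ct: CrossTab2x2, alpha: float = 0.05) -> TrackingStatistics:
    """RR, sensitivity, specificity and PPV for a 2x2 table.

    Proportions are reported in percent with Wald intervals; statistics
    with an empty margin (and an RR whose interval is undefined) are
    reported as ``None``.
    """
    try:
        rr = relative_risk(ct, alpha)
    except ValueError:
        rr = None
    sens = _wald_percent(ct.a, ct.a + ct.c, alpha) if ct.a + ct.c > 0 else None
    spec = _wald_percent(ct.d, ct.b + ct.d, alpha) if ct.b + ct.d > 0 else None
    ppv = _wald_percent(ct.a, ct.a + ct.b, alpha) if ct.a + ct.b > 0 else None
    return TrackingStatistics(rr=rr, sensitivity=sens, specificity=spec, ppv=ppv, n=ct.total)


def _check_bins(bins: Sequence[float], name: str) -> np.ndarray:
    edges = np.asarray(bins, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError(f"{name} must be strictly increasing bin edges, got {bins}")
    return edges


def stratified_tracking(
    pairs: pd.DataFrame,
    age_bins: Optional[Sequence[float]] = None,
    interval_bins: Sequence[float] = DEFAULT_INTERVAL_BINS,
    min_count: int = 50,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screening statistics per (initial-age, follow-up-interval) stratum.

    ``age_bins`` defaults to whole years spanning the observed initial
    ages; ``interval_bins`` defaults to <2, 2-4.9, 5-7.9 and >=8 years.
    Strata with fewer than ``min_count`` pairs are reported with counts
    but suppressed statistics.  Bins are half-open on the right.
    """
    if age_bins is None:
        lo = int(np.floor(pairs["first_age"].min())) if len(pairs) else 2
        hi = int(np.floor(pairs["first_age"].max())) + 1 if len(pairs) else 10
        age_bins = np.arange(lo, hi + 1, dtype=float)
    age_edges = _check_bins(age_bins, "age_bins")
    int_edges = _check_bins(interval_bins, "interval_bins")

    df = pairs.copy()
    df["_age_stratum"] = pd.cut(df["first_age"], age_edges, right=False)
    df["_interval_stratum"] = pd.cut(df["interval_years"], int_edges, right=False)
    df = df.dropna(subset=["_age_stratum", "_interval_stratum"])

    rows = []
    grouped = df.groupby(["_age_stratum", "_interval_stratum"], observed=False)
    for (age_s, int_s), block in grouped:
        ct = crosstab(block) if len(block) else CrossTab2x2(0, 0, 0, 0)
        row = {
            "age_stratum": age_s,
            "interval_stratum": int_s,
            "n": ct.total,
            "a": ct.a,
            "b": ct.b,
            "c": ct.c,
            "d": ct.d,
            "suppressed": ct.total < min_count,
        }
        if ct.total >= min_count:
            stats = screening_stats(ct, alpha)
            for name, est in (
                ("rr", stats.rr),
                ("sensitivity", stats.sensitivity),
                ("specificity", stats.specificity),
                ("ppv", stats.ppv),
            ):
                row[name] = est.estimate if est else np.nan
                row[f"{name}_lo"] = est.lower if est else np.nan
                row[f"{name}_hi"] = est.upper if est else np.nan
        else:
            for name in ("rr", "sensitivity", "specificity", "ppv"):
                row[name] = row[f"{name}_lo"] = row[f"{name}_hi"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def persistence_patterns(triples: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of the 8 obesity-status patterns across the
    three age windows, with mean BMIz per window per pattern.

    Percentages are reported against three denominators: all children,
    children with early obesity (obese in window 1) and children with
    late obesity (obese in window 3); patterns outside a subgroup have
    NaN for that percentage.
    """
    needed = {"w1_obese", "w2_obese", "w3_obese", "w1_bmiz", "w2_bmiz", "w3_bmiz"}
    missing = needed - set(triples.columns)
    if missing:
        raise ValueError(f"triples missing columns: {sorted(missing)}")
    total = len(triples)
    n_early = int(triples["w1_obese"].sum())
    n_late = int(triples["w3_obese"].sum())
    rows = []
    for p1 in (False, True):
        for p2 in (False, True):
            for p3 in (False, True):
                sel = triples[
                    (triples["w1_obese"] == p1)
                    & (triples["w2_obese"] == p2)
                    & (triples["w3_obese"] == p3)
                ]
                n = len(sel)
                rows.append(
                    {
                        "w1_obese": p1,
                        "w2_obese": p2,
                        "w3_obese": p3,
                        "n": n,
                        "pct_total": 100.0 * n / total if total else np.nan,
                        "pct_early_obesity": (
                            100.0 * n / n_early if (p1 and n_early) else np.nan
                        ),
                        "pct_late_obesity": (
                            100.0 * n / n_late if (p3 and n_late) else np.nan
                        ),
                        "mean_bmiz_w1": sel["w1_bmiz"].mean() if n else np.nan,
                        "mean_bmiz_w2": sel["w2_bmiz"].mean() if n else np.nan,
                        "mean_bmiz_w3": sel["w3_bmiz"].mean() if n else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def prevalence(
    records: pd.DataFrame,
    by: Sequence[str],
    alpha: float = 0.05,
    status_column: str = "obese",
) -> pd.DataFrame:
    """Obesity prevalence (percent, Wald CI) per group.

    Call on the output of ``sample_one_per_cell`` so each child
    contributes one record per cell.  Empty groups are absent from the
    output rather than reported as zero.
    """
    rows = []
    for keys, block in records.groupby(list(by), observed=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        n = len(block)
        if n == 0:
            continue
        k = int(block[status_column].sum())
        ci = _wald_percent(k, n, alpha)
        row = dict(zip(by, keys))
        row.update(
            {
                "n": n,
                "n_obese": k,
                "prevalence_pct": ci.estimate,
                "lower": ci.lower,
                "upper": ci.upper,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def max_sensitivity_bound(prev_young_pct: float, prev_old_pct: float) -> float:
    """Upper bound (percent) on the sensitivity of obesity at a young age
    for obesity at an older age, given the two prevalences in percent.

    Every child obese young who remains obese old is part of the older
    prevalence, so sensitivity cannot exceed the prevalence ratio.
    """
    if prev_old_pct <= 0:
        raise ValueError("older-age prevalence must be positive")
    if prev_young_pct < 0:
        raise ValueError("prevalence cannot be negative")
    return min(100.0, 100.0 * prev_young_pct / prev_old_pct)
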