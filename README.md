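# growthtrack

Cleaning of longitudinal pediatric EHR weight/height records and
analysis of BMI and obesity tracking from childhood into adolescence.

Electronic health records hold millions of routinely collected weights
and heights, but they are noisy: values carried forward from a previous
visit, pounds recorded as kilograms, transposed digits, duplicate rows
on the same date.  `growthtrack` is for epidemiologists and biostatisticians
who want to (1) clean such data with longitudinal, per-child rules and
(2) quantify how well obesity at one examination predicts obesity at a
later one.

## What it computes

**Growth reference (LMS).**  A measurement `X` against a sex/age
reference with Box-Cox power `L`, median `M` and coefficient of
variation `S` has z-score

```
z = ((X/M)^L - 1) / (L*S)        (z = ln(X/M)/S as L -> 0)
```

Obesity is BMI at or above the reference 95th percentile; severe
obesity at or above 120% of that value.  Error screening uses the
*modified* z-score: distance from `M` in units of half the distance
between `M` and the ±2 SD reference values, which stays meaningful for
grossly wrong values.

**Cleaning.**  Unit conversion and mixed-unit exclusion; exclusion of
children with >100 visits; same-day duplicate resolution; exact-equality
carried-forward detection (with the growth-aware exception that an
unchanged height in boys ≥17 y / girls ≥16 y may be attained height);
EWMA outlier flagging — each measurement's modified z is compared with a
time-weighted mean of the child's other visits, weights
`(gap_days + 5)^-1.5`, threshold 3.5, worst-first with recomputation;
height decreases >3 cm; modified BMIz ≥25 or BMI ≥150; and a cohort-level
robust-smoother screen (residual above the pooled 99.95th percentile
*and* >10 kg) for remaining unit-scale weight errors.

**Tracking statistics.**  With the first-by-last obesity 2×2 table
(a, b, c, d), the package reports RR = [a/(a+b)]/[c/(c+d)] with the Katz
log-normal interval, sensitivity a/(a+c), specificity d/(b+d) and PPV
a/(a+b) with Wald intervals, stratified by initial age and follow-up
interval; three-age persistence patterns; grouped prevalence from
one-record-per-cell sampling; and the prevalence-ratio bound
`100 * prev_young / prev_old` on the sensitivity of early obesity for
later obesity.

**Synthetic EHR generator.**  Because real pediatric EHR extracts are
proprietary, a calibrated generator provides test data: latent BMIz
follows a stationary continuous-time AR(1) (correlation `rho^gap_years`,
defaults tuned so the correlation over 3.7 years is 0.80), obesity
prevalence 13.4% at the first exam and rising with age, ~6.5 visits per
child over ~4 years, a 90/6/4% US-standard/metric/mismatched unit mix,
and controlled injection of every error mode above with truth labels.

## Worked example

`python examples/tracking_statistics.py` (5,000 synthetic children):

```
eligible pairs: 4354
2x2 table: a=398 b=160 c=462 d=3334
relative risk     5.9  (95% CI 5.3, 6.5)
sensitivity %    46.3  (95% CI 42.9, 49.6)
specificity %    95.4  (95% CI 94.7, 96.1)
PPV %            71.3  (95% CI 67.6, 75.1)

by follow-up interval (pooled ages):
interval_stratum    n   rr  sensitivity  ppv
      [1.0, 2.0)  664 11.7         63.0 81.0
      [2.0, 5.0) 2320  7.4         53.8 75.6
      [5.0, 8.0) 1091  3.5         31.3 59.8
      [8.0, inf)  279  2.4         23.1 48.4
```

Children obese at their first exam are ~6 times as likely to be obese at
the last exam; 71% of them still are (PPV), yet fewer than half of the
children obese at the end were already obese at the start (sensitivity)
— and the association weakens steadily as the follow-up interval grows.
The other scripts in `examples/` demonstrate the generator, the cleaning
report and error recovery, three-age persistence patterns, and the
prevalence-ratio sensitivity bound.

A thin CLI mirrors the pipeline:

```
growthtrack simulate --n-children 2000 --seed 7 --out data/
growthtrack clean --in data/visits.csv --out cleaned.csv --report report.json
growthtrack cohort --in cleaned.csv --out pairs.csv
growthtrack analyze --pairs pairs.csv --out results/
```

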