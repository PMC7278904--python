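# Methods

## Scope and design

`growthtrack` implements a complete desk-reproducible version of a
common EHR growth-data workflow: LMS-based BMI metrics, longitudinal
cleaning of weight/height measurements, first/last-exam cohort
construction, and screening-style obesity-tracking statistics.  Because
the data this workflow targets are proprietary, the package ships a
first-class synthetic generator whose defaults encode the study
conditions the analysis assumes; every downstream stage is tested
against it.

## Growth reference

z-scores use the LMS transform `z = ((X/M)^L - 1)/(L*S)`, implemented
with `expm1`/`log1p` so the removable singularity at `L = 0` is handled
smoothly (the logarithmic branch is taken for `|L| < 1e-8`).  The
inverse requires `1 + L*S*z > 0`; values outside that domain are
rejected with a diagnostic rather than silently clipped.

The modified z-score divides the distance from the median by half the
distance between the median and the +2 SD reference value (above the
median) or the −2 SD value (below).  Unlike the ordinary z-score — which
compresses grossly wrong values into a narrow range when `L` is strongly
negative — it grows roughly linearly with the measurement, which is what
an error screen needs.  It equals ±2 exactly at the ±2 SD reference
values and is undefined only when `2|L*S| >= 1` (no real growth
reference approaches that region).

Reference tables are tabulated by sex, measure and age in months; `L`,
`M`, `S` are each interpolated linearly in age, exactly at the knots.
The shipped table (`synthetic_reference()`) is synthetic but
shape-realistic: median BMI dips in early childhood and rises through
adolescence, `L` is near −2 for BMI (right-skew), heights are monotone
with decelerating velocity, and weight medians are derived from the BMI
and height medians so the three measures cohere.  Any real LMS table in
the documented CSV schema (`sex,measure,age_months,L,M,S`) can be
loaded instead; no analysis in the package depends on the synthetic
table's particular values.

Obesity cutoffs are inclusive: BMI at or above the 95th percentile, and
severe obesity at or above 120% of the 95th-percentile BMI.

## Synthetic cohort generator

Per child: sex is Bernoulli (48% female); the first exam age is uniform
on 2–9 y; visit counts are `1 + Poisson(5.5)` capped at 30 (≈6.5 visits
per child); inter-visit gaps are exponential with mean 0.73 y, floored
at one day, giving a mean first-to-last span of ≈4 y; visits past age
19 are dropped.  A configurable small fraction of children are "high
utilizers" with 101–140 visits compressed into ≈8 y, so the >100-visit
exclusion has something to exclude.

Latent BMIz is `mu(age) + zeta(t)`, where `zeta` is a stationary
standard-normal AR(1) in continuous time (`corr = rho^gap_years`; the
default `rho = 0.80^(1/3.7)` makes the correlation over a typical
3.7-year follow-up equal 0.80) and `mu(age)` rises linearly at
0.062 SD/y — the slope implied by prevalence rising from ~8% at age 2
to ~20% at ages ≥9 under a normal latent model.  The intercept is
solved numerically so the first-exam obesity prevalence, averaged over
the uniform first-age distribution, equals the configured 13.4%.
Height-for-age z follows a slower AR(1) (`rho = 0.95`/y); height comes
from the height reference, BMI from the BMI reference, and weight is
solved from `BMI * (height/100)^2`, so the three recorded measures are
mutually consistent.  Latent z is clipped just inside the LMS inverse
domain (`1 + L*S*z > 0`) before mapping to values; this mirrors the way
LMS references compress the far upper tail and affects well under 1% of
draws, all far above the obesity cutoff.

Recorded values get multiplicative log-normal measurement noise (SD 1%
for weight, 0.5% for height) *before* rounding and error injection, so
the cleaning rules must tolerate benign noise.  Units are assigned per
child (90% lb/in, 6% kg/cm, 4% mismatched), values rounded as a clinic
would record them (0.1 lb / 0.01 kg / 0.1 in / 0.1 cm).

Error injection gives each measurement at most one mode: carried
forward (copies the child's previous *recorded* value, so chains of
copies reproduce naturally), unit swap (the same number expressed in
the other unit but keeping the label), transcription (an even split of
×10 / ÷10 decimal shifts and adjacent-digit transpositions), and
same-day duplicates (an extra row on the same date with ~10% perturbed
values).  Every corruption is labeled in a side table keyed by a
synthetic `record_id`; the truth tables are never visible to cleaning.
Identical configuration and seed reproduce the tables byte for byte.

What the generator does **not** emulate: secular calendar trends,
practice- or clinician-level clustering, race/ethnicity structure,
informative visit timing (sicker children visiting more), or
heteroscedastic tracking (real BMIz is more stable in the far tail than
a homoscedastic AR(1) implies).  Passing tests therefore demonstrate
correctness of the algorithms under these stated conditions, not
performance on any particular real dataset.

## Cleaning pipeline

Stages run in this order: unit conversion and mixed-unit exclusion;
>100-visit child exclusion; same-day resolution; then, per child, a
loop of carried-forward detection, EWMA outlier flagging (weight and
height), height-decrease flagging and extreme-value exclusion until no
rule fires; finally the cohort-level smoother screen.

Design choices worth recording:

* **Record-scope disposition.**  A flag names the offending measurement
  but excludes the whole record.  Downstream analysis needs both
  measurements anyway, and record scope makes the pipeline exactly
  idempotent: the retained set the detection loop converges on is the
  same set a second cleaning pass would see.
* **Fixpoint instead of a single pass.**  A single ordered pass is not
  idempotent — excluding a mid-trajectory value can create a new
  adjacent pair of equal weights, and EWMA expectations shift as gross
  errors are removed.  The loop re-runs the four per-child rules until
  stable (in practice 1–3 iterations; hard cap 10).
* **EWMA details.**  The expected modified z at a visit is the weighted
  mean of the child's other retained visits with weights
  `(gap_days + 5)^-1.5`; deviations beyond 3.5 (configurable) are
  excluded worst-first.  For a two-visit child the two deviations are
  exactly opposite, so ties break toward the value farther from the
  reference median.  Children with a single retained measurement skip
  the rule.
* **Carried-forward heights.**  Candidates are heights equal to the
  previous retained height.  They are excluded when they follow a
  height already flagged as an error (checked on raw adjacency, since
  the flagged row has left the retained set) or when the value has
  persisted for more than 3 months (91.3 days) in boys <17 y / girls
  <16 y, measured from the start of the equal-value run.  Equal weights
  are excluded unconditionally, by exact float equality — unit
  conversion is a common multiplicative factor per child, so copied
  values stay exactly equal.
* **Same-day duplicates** keep the row whose modified z-scores are
  jointly closest to the EWMA expectation computed from the child's
  other dates; with no other dates the first row by input order is
  kept (dropping all would discard the child's only data).
* **Smoother screen.**  Each child's retained weights are smoothed
  against age with a robust local-linear scatterplot smoother (LOWESS,
  two robustifying iterations, span adapted to the visit count, minimum
  five points).  A child is excluded when any absolute residual exceeds
  both the cohort-pooled 99.95th percentile and 10 kg.  The pooled
  quantile is re-evaluated after each round of exclusions until stable;
  whenever the quantile sits below 10 kg (as it does at scale) this
  coincides with a single application.  On error-free synthetic data
  this screen is the only rule with a visible false-positive cost
  (~1% of children, whose far-tail weight volatility produces >10 kg
  residuals); the per-measurement rules retain >99%.
* The classic fixed biologically-implausible-value cutoffs are
  deliberately not applied; only the modified BMIz ≥25 / BMI ≥150 rule
  is, because extreme-but-consistent trajectories are often real.

The cleaning report counts rows per flag code and attributes each
excluded record to a single primary cause (first flag in stage order),
so the per-code exclusions sum exactly to `records_in − records_out`.

## Cohort construction

Age is `(exam_date − July 1 of birth_year)/365.25` — EHR extracts carry
birth year only, so the mid-year anchor is the natural unbiased choice.
The tracking design takes the earliest retained visit at ages 2–<10 y
as the first exam and the child's latest retained visit as the last,
requiring ≥1 y between them; children failing either condition are
ineligible (a value, not an error).  The three-age design takes the
earliest retained visit in each of 2–<4, 6–<8 and ≥10 y.  Prevalence
estimation samples one record per child per (age-group × calendar-year)
cell, uniformly at random and reproducibly from a seed, so frequent
attenders do not dominate.

## Statistics

Proportions (sensitivity, specificity, PPV, prevalence) use Wald
normal-approximation intervals on the proportion scale, reported in
percent and clipped to [0, 100]; at the cohort sizes this package
targets the Wald and score intervals agree to well past the reported
precision.  The relative risk uses the Katz log-normal interval with no
continuity correction; tables with an empty margin or zero unexposed
risk are rejected with a diagnostic rather than patched.  Stratified
output suppresses statistics (but reports counts) for strata with fewer
than 50 pairs by default, since tiny strata produce unstable ratios.
The prevalence-ratio bound on sensitivity is `100 * prev_young /
prev_old`, capped at 100%: every early-and-late obese child is included
in the later prevalence, so sensitivity cannot exceed the ratio.

## Problem sizes and numerical choices

The test suite exercises the pipeline at 5,000 children (error
recovery: ≥90% of injected carried-forward weights flagged, ≥80% of
decimal shifts, ≤2% measurement-level false flags, idempotence) and
20,000 children (generator calibration to ±0.03 of the 0.80 tracking
correlation and 3 SE of the 13.4% prevalence; rank orderings of RR
across follow-up bins and sensitivity across initial-age bins).  These
sizes give Monte-Carlo standard errors several times smaller than the
margins being asserted while keeping the whole suite under a minute of
generator/cleaning work.  Seeds are fixed throughout; `hypothesis`
property tests run derandomized.

## Known limitations

* The cleaning rules implement the documented screen, not every
  sub-rule of any particular reference implementation; the smoother is
  a robust LOWESS rather than a variable-span supersmoother (pluggable
  via configuration).
* Wald intervals can misbehave for very small cells; the package
  targets large-cohort use and suppresses small strata instead.
* The generator's homoscedastic AR(1) overstates weight volatility in
  the extreme upper tail, which is why the smoother screen shows its
  ~1% child-level false-positive rate there; on real data the same
  screen is reported to remove only a few children per million.
* Modified z-scores require the ±2 SD reference values to exist
  (`2|L*S| < 1`), true of all practical growth references.
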