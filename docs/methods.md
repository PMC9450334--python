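# Methods

## Scoring engine

Each system is a declarative `ScoreDefinition`: closed integer age bands,
male points, a family-history rule (any affected first-degree relative, or
≥ 2 for the 8-point system), a smoking rule (ever-smoker, or strictly
> 18.5 pack-years for the 8-point system), an optional BMI threshold rule
and optional diabetes points, plus the published cut-off.  All points are
stored as integers in half-point units (value × 2), so the 8-point
system's 0.5 and 3.5 items are exact and score totals compare without
floating point — ties must be exact because the c-statistic counts them at
one half.

Boundary conventions are preserved exactly as published and deliberately
differ between systems: BMI ≥ 25 (CNP, KCS), ≥ 23 (Modified APCS), but
strictly > 22.5 (8-point).  Construction-time validation enumerates a
factor grid and requires the attained maximum to equal the declared
maximum (7, 6, 8, 6, 8 points).

Two systems (CNP, Modified APCS) publish age bands that stop at 70.
Following the validation convention, ages 71–74 score as the top published
band (1 and 2 points respectively); this is encoded as an explicit extra
band.  Below 50 those two systems have no published band, and scoring
raises rather than silently assigning 0 — the intended population is
50–74, and extrapolation would be invented.  APCS, KCS and the 8-point
system publish an under-50 band and score it.

## Validation statistics

All statistics operate on a 2×2 of stratum × outcome counts
(`a` CAN/high, `b` negative/high, `c` CAN/non-high, `d` negative/non-high).

- **Proportions** (detection rates, high-risk rate, sensitivity,
  specificity, PPV, NPV): exact Clopper–Pearson 95% intervals
  (beta-quantile form via statsmodels).  The exact interval was chosen
  because it reproduces published validation intervals where Wilson-type
  intervals do not.
- **Relative risk**: Katz log method,
  `exp(ln RR ± z·√(1/a − 1/(a+b) + 1/c − 1/(c+d)))`.  With one zero event
  cell the point estimate is returned with an unbounded, flagged interval;
  with both zero the statistic raises.
- **Chi-square**: unadjusted Pearson on the 2×2 (1 df, no continuity
  correction) — that is what the name denotes; no multiplicity adjustment
  is applied across the five scores.
- **c-statistic**: midrank (Mann–Whitney) form, identical by construction
  to brute-force pair enumeration with ties counted half; variance by
  DeLong's structural components, CI clipped to [0, 1].
- **Binary NRI**: `(up_e − down_e)/n_e + (down_ne − up_ne)/n_ne` with the
  original Pencina z-test variance
  `(up_e + down_e)/n_e² + (up_ne + down_ne)/n_ne²`.  A later refinement
  subtracts the squared net-movement proportion inside each class; on
  reclassification tables of this validation's size the two differ in the
  third decimal of the SE, and the original form is the one that matches
  published intervals for this design, so it is the default.  A
  self-comparison has SE 0; it is returned as a degenerate result with
  p = NaN rather than raising.
- **Quoting convention**: validation reports quote percentages to 2
  decimals and typically form NRI interval bounds from the rounded point
  and the rounded half-width (z × SE%, SE% itself quoted to 2 dp).
  `format_nri_ci_published_style` reproduces that convention; the
  full-precision bounds are always available on the result object.
- **Resource load**: NNS = (a+b)/a rounded half-up to integer; the
  no-score baseline is N / total CAN.  The CI inverts the exact
  Clopper–Pearson PPV interval and says so in its method label, since NNS
  interval constructions vary between reports and are often unstated.
- Display rounding is decimal half-up everywhere (10.5 → 11, 16.11 → 16);
  internal computation keeps full precision.

## Synthetic cohort generator

The generator emulates the *marginals* of an urban-screening validation
cohort: age bands {50–54, 55–59, 60–64, 65–69, 70–74} with probabilities
(0.2417, 0.2406, 0.2616, 0.2084, 0.0477); P(male) = 0.5044;
P(ever-smoker) = 0.4346; BMI categories {<23, 23–25, ≥25} with
(0.2189, 0.2761, 0.5050) and a uniform draw within the category (overall
support 18–35 kg/m²); P(diabetes) = 0.0998; P(family history) = 0.1524.
Factors are sampled independently — the source reports only marginals, and
independence is the minimal assumption.  Consequently the generator is not
expected to reproduce the source cohort's joint stratification pattern
(its high-risk rates, RRs or reclassification cells); it exists so every
pipeline stage is testable on realistic, reproducible data.

Quantities the source does not report get documented defaults: smokers'
pack-years are log-normal with median 15 and σ = 0.7 (≈ 38% of smokers
exceed the 8-point threshold of 18.5 pack-years); non-smokers have 0.
Among family-history-positive subjects, 10% have ≥ 2 affected relatives,
so the 8-point family-history item is exercised on both sides.

The outcome is Bernoulli from a logistic model on the discrete factors
(age band, male, smoker, BMI category, diabetes, family history).  Default
log-odds are a mild monotone gradient — ln 1.3 per age band, ln 1.6
(male), ln 1.5 (smoker), (0, ½ ln 1.3, ln 1.3) over BMI categories,
ln 1.4 (diabetes), ln 1.6 (family history) — chosen once so the five
scores' c-statistics on large cohorts sit near 0.6, the discrimination
regime reported for such scores in external validation (observed ≈
0.59–0.62 at n = 10⁵ with the default seed series).  These are generator
knobs, not estimates of any cohort's effects.

The intercept is calibrated so the *expected* prevalence equals the target
(default 6.21%): the expectation is computed exactly by summing the
logistic model over the 240-cell discrete factor grid (independence makes
the joint distribution a product), and the intercept is found by Brent
root-finding on that monotone map, accurate to ~1e-9.  The analytic
high-risk fraction of any score under the generator
(`expected_stratum_fraction`) enumerates integer ages within bands, the
pack-year tail probability and the BMI-threshold position inside each
uniform category; it serves as an independent oracle for simulated
stratification proportions.

A single seeded NumPy `default_rng` stream drives all draws in a fixed
order, so a (config, seed) pair reproduces a cohort bit-for-bit; the seed
and calibrated intercept are recorded in the generator report.

## Eligibility and I/O

Cohorts are UTF-8 CSV with a required header; booleans are accepted as
{0, 1, yes, no, true, false} and sex as {male, female, m, f},
case-insensitively after trimming; missing cells are empty or "NA".
Rows violating type invariants (age outside [18, 120], BMI outside
(10, 80), negative pack-years…) are rejected with 1-based row-numbered
diagnostics.  The eligibility filter retains ages 50–74 with a completed
colonoscopy outcome and complete risk factors; pack-years is required only
when the 8-point score is requested, mirroring a complete-case analysis
without discarding subjects the other four systems can score.  Each
exclusion is counted under its first failing reason in a fixed order, so
reason counts plus retained count always equal the input count.

## Problem sizes

The default test run uses cohorts of 10–60k subjects for generator
properties, one 100k cohort for marginal-recovery checks, 100 random
instances (n ≤ 500) for the c-statistic oracle and 10⁵ randomized pairs for
score monotonicity; the whole suite completes in well under a minute on a
single core.  The acceptance script draws one 100k cohort.

## Known limitations

- Independent factors: no correlation structure, no copulas; joint-pattern
  quantities of real cohorts are out of reach by design.
- Real screening cohorts recruited through high-risk triage are enriched
  relative to average-risk populations; the generator does not model a
  triage stage.
- The c-statistic needs subject-level scores, so published c-statistics
  cannot be recomputed from published counts; the implementation is
  instead verified against exhaustive pair enumeration.
- Score cut-offs are applied as published; no cut-off optimisation or
  recalibration is performed, and no IDI / calibration-curve /
  decision-curve analysis is included.
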