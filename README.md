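# crcscreen

External-validation toolkit for the Asia-Pacific colorectal-screening risk
scores.

## The problem

Colonoscopy is the gold standard for detecting colorectal advanced
neoplasia (CAN: colorectal cancer, or any adenoma ≥ 1 cm, with high-grade
dysplasia or tubular-villous histology), but colonoscopy capacity is
limited.  Questionnaire-based point scores are used to triage asymptomatic
screening participants: each score sums points over age band, sex, family
history of CRC in first-degree relatives, smoking and (in modified
versions) BMI and diabetes, and refers subjects at or above a published
cut-off to colonoscopy.  Five such systems circulate in Asia-Pacific
screening practice — APCS, CNP (colorectal neoplasia predict), KCS (Korean
colorectal screening), Modified APCS and the 8-point risk score — and a
screening programme choosing among them needs all five validated on the
same cohort.

`crcscreen` is written for epidemiologists and screening-programme
statisticians doing exactly that comparison.  It provides:

- **`crcscreen.scores`** — the five scoring systems as declarative rules
  (points kept in exact half-point integer units; published boundary
  conventions preserved verbatim, e.g. BMI ≥ 25 for CNP/KCS but BMI > 22.5
  for the 8-point score; ages 71–74 mapped to the top published band where
  a system's bands stop at 70);
- **`crcscreen.stats`** — the validation statistics: per-stratum detection
  rates and the high-risk rate with exact Clopper–Pearson 95% CIs, relative
  risk with the Katz log CI, unadjusted Pearson chi-square, sensitivity /
  specificity / PPV / NPV, the tie-corrected c-statistic
  `c = [#(case > control) + ½·#ties] / (n_case·n_control)` with DeLong
  variance, the binary net reclassification improvement
  `NRI = (up_e − down_e)/n_e + (down_ne − up_ne)/n_ne` with the Pencina
  z-test, and the colonoscopy resource load (number needed to scope,
  NNS = n_high / CAN_high, rounded half-up);
- **`crcscreen.simulate`** — a synthetic-cohort generator whose marginals
  emulate a published urban-screening validation cohort (50.44% male,
  43.46% ever-smokers, 9.98% diabetes, 15.24% family history, five age
  bands on 50–74) with the CAN prevalence calibrated to 6.21% by exact
  summation of the logistic outcome model over the factor grid;
- **`crcscreen.cohort`** — CSV I/O with documented normalization and the
  study eligibility filter (age 50–74, completed colonoscopy, complete
  risk factors);
- **`crcscreen.cli`** — `crcscreen simulate | score | validate | report`.

## Worked example

Recompute a published validation from its stratum × outcome counts.  The
APCS table below is `a=82` CAN among 891 high-risk and `c=30` CAN among 913
non-high-risk subjects:

```python
from crcscreen import TwoByTwo, relative_risk, diagnostic_metrics, resource_load

t = TwoByTwo(a=82, b=809, c=30, d=883)
print(relative_risk(t).rounded())          # (2.8, 1.86, 4.21)
print(diagnostic_metrics(t)["sensitivity"].rounded())  # (73.21, 64.02, 81.14)
print(resource_load(t).point)              # 11.0
```

The relative risk 2.80 (95% CI 1.86–4.21) says CAN is detected 2.8× more
often in the APCS high-risk stratum; sensitivity 73.21% is the share of all
CAN cases the cut-off captures; NNS 11 means eleven high-risk colonoscopies
per CAN found (versus 16 when scoping everyone).

Or run the whole pipeline on a simulated cohort:

```sh
crcscreen validate --simulate-n 20000 --seed 7 --outdir out/
```

which writes `out/report.json` (deterministic, schema-validated) and
`out/report.txt` with the characteristics, stratification, performance,
reclassification-vs-APCS and resource-load tables.

The numbered drivers under `analysis/` narrate the full study:
`01_simulate_cohort.py` (draw calibrated cohorts), `02_validate_scores.py`
(five-score validation of the simulated cohort),
`03_published_reproduction.py` (recompute every published count-derived
statistic).

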