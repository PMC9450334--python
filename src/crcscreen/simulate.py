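"""Synthetic screening-cohort generator.

Draws reproducible cohorts whose risk-factor marginals emulate a published
urban-screening validation cohort (age-band mix, 50.44% male, 43.46% ever-smokers, BMI
category split 21.89 / 27.61 / 50.50%, 9.98% diabetes, 15.24% family
history of CRC in first-degree relatives) and whose CAN outcome follows a
logistic model on the discrete risk factors, with the intercept calibrated
by exact summation over the factor grid so the expected prevalence hits a
target (default 6.21%).

Factors are sampled independently — the source cohort reports only
marginals, so independence is the minimal assumption.  Quantities the
source does not report get documented defaults: smokers' pack-years are
log-normal (median 15, sigma 0.7), so a realistic fraction crosses the
8-point system's 18.5 pack-year threshold; among family-history-positive
subjects 10% have two or more affected relatives, exercising the 8-point
family-history item; BMI is uniform within its sampled category.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .cohort import Cohort, SubjectRecord, MALE, FEMALE, CAN, NEGATIVE
from .scores import ScoreDefinition, SMOKE_EVER, SMOKE_PACK_YEARS_GT

__all__ = [
    "GeneratorConfig", "GeneratorReport", "CalibrationError",
    "default_config", "expected_prevalence", "calibrate_intercept",
    "generate", "expected_stratum_fraction",
]

_LN = math.log


class CalibrationError(Exception):
    """The target prevalence cannot be reached by shifting the intercept."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterisation of the synthetic cohort.

    Probability vectors must sum to 1 (tolerance 1e-12).  The outcome model
    is logistic: logit P(CAN) = intercept + age_band_lor[band] +
    male_lor * male + smoker_lor * smoker + bmi_lor[cat] +
    diabetes_lor * diabetes + family_history_lor * (fdr_crc_count >= 1).
    When ``target_prevalence`` is set the intercept is recalibrated so the
    grid-exact expected prevalence equals it.
    """

    n: int = 1804
    seed: int = 0
    age_bands: tuple[tuple[int, int], ...] = ((50, 54), (55, 59), (60, 64), (65, 69), (70, 74))
    age_band_probs: tuple[float, ...] = (0.2417, 0.2406, 0.2616, 0.2084, 0.0477)
    p_male: float = 0.5044
    p_smoker: float = 0.4346
    #: log pack-years ~ Normal(log_pack_years_mu, sigma) for smokers; 0 otherwise.
    log_pack_years_mu: float = _LN(15.0)
    log_pack_years_sigma: float = 0.7
    bmi_categories: tuple[tuple[float, float], ...] = ((18.0, 23.0), (23.0, 25.0), (25.0, 35.0))
    bmi_category_probs: tuple[float, ...] = (0.2189, 0.2761, 0.5050)
    p_diabetes: float = 0.0998
    p_family_history: float = 0.1524
    #: P(fdr_crc_count >= 2 | any family history).
    p_fdr_ge2_given_fh: float = 0.10
    # Outcome-model log-odds; a mild monotone gradient over the score factors.
    age_band_lor: tuple[float, ...] = (0.0, _LN(1.3), 2 * _LN(1.3), 3 * _LN(1.3), 4 * _LN(1.3))
    male_lor: float = _LN(1.6)
    smoker_lor: float = _LN(1.5)
    bmi_lor: tuple[float, ...] = (0.0, 0.5 * _LN(1.3), _LN(1.3))
    diabetes_lor: float = _LN(1.4)
    family_history_lor: float = _LN(1.6)
    intercept: float = -3.0
    target_prevalence: Optional[float] = 0.0621

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name, probs in (
            ("age_band_probs", self.age_band_probs),
            ("bmi_category_probs", self.bmi_category_probs),
        ):
            if abs(sum(probs) - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1 (got {sum(probs)!r})")
            if any(p < 0 for p in probs):
                raise ValueError(f"{name} must be non-negative")
        if len(self.age_band_probs) != len(self.age_bands):
            raise ValueError("age_band_probs length mismatch")
        if len(self.bmi_category_probs) != len(self.bmi_categories):
            raise ValueError("bmi_category_probs length mismatch")
        if len(self.age_band_lor) != len(self.age_bands):
            raise ValueError("age_band_lor length mismatch")
        if len(self.bmi_lor) != len(self.bmi_categories):
            raise ValueError("bmi_lor length mismatch")


def default_config(n: int = 1804, seed: int = 0, **overrides) -> GeneratorConfig:
    """The study-conditions configuration (marginals above, prevalence 6.21%)."""
    return replace(GeneratorConfig(n=n, seed=seed), **overrides)


@dataclass(frozen=True)
class GeneratorReport:
    """Realized marginals of one generated cohort; reproducible given seed."""

    n: int
    seed: int
    intercept: float
    realized: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"n": self.n, "seed": self.seed, "intercept": self.intercept,
             "realized": {k: self.realized[k] for k in sorted(self.realized)}},
            sort_keys=True, indent=2,
        )


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _grid_cells(config: GeneratorConfig):
    """Joint distribution over the discrete outcome-model factors.

    Yields (weight, band_index, male, smoker, bmi_cat, diabetes, fh);
    exact because factors are independent by construction.
    """
    for bi, pb in enumerate(config.age_band_probs):
        for male, pm in ((True, config.p_male), (False, 1 - config.p_male)):
            for smoker, ps in ((True, config.p_smoker), (False, 1 - config.p_smoker)):
                for ci, pc in enumerate(config.bmi_category_probs):
                    for diab, pd_ in ((True, config.p_diabetes), (False, 1 - config.p_diabetes)):
                        for fh, pf in ((True, config.p_family_history), (False, 1 - config.p_family_history)):
                            w = pb * pm * ps * pc * pd_ * pf
                            if w > 0:
                                yield w, bi, male, smoker, ci, diab, fh


def _linpred(config: GeneratorConfig, intercept: float, bi: int, male: bool,
             smoker: bool, ci: int, diab: bool, fh: bool) -> float:
    return (
        intercept
        + config.age_band_lor[bi]
        + (config.male_lor if male else 0.0)
        + (config.smoker_lor if smoker else 0.0)
        + config.bmi_lor[ci]
        + (config.diabetes_lor if diab else 0.0)
        + (config.family_history_lor if fh else 0.0)
    )


def expected_prevalence(config: GeneratorConfig, intercept: Optional[float] = None) -> float:
    """Exact expected CAN prevalence by summation over the factor grid."""
    b0 = config.intercept if intercept is None else intercept
    return sum(
        w * _sigmoid(_linpred(config, b0, *cell))
        for w, *cell in _grid_cells(config)
    )


def calibrate_intercept(config: GeneratorConfig, tol: float = 1e-9) -> float:
    """Intercept for which the expected prevalence equals the target.

    The expectation is strictly increasing in the intercept, so monotone
    root bracketing (Brent) converges; the result satisfies the target
    within 1e-6 by construction.
    """
    target = config.target_prevalence
    if target is None:
        return config.intercept
    if not 0.0 < target < 1.0:
        raise CalibrationError(f"target prevalence {target!r} outside (0, 1)")
    f = lambda b0: expected_prevalence(config, b0) - target
    lo, hi = -40.0, 40.0
    if f(lo) > 0 or f(hi) < 0:
        raise CalibrationError("target prevalence unattainable within intercept bounds")
    return float(brentq(f, lo, hi, xtol=tol))


def generate(config: GeneratorConfig) -> tuple[Cohort, GeneratorReport]:
    """Draw one cohort: independent factors, logistic CAN outcome.

    A single seeded PRNG stream drives every draw, so identical
    (config, seed) pairs give identical cohorts.
    """
    intercept = calibrate_intercept(config)
    rng = np.random.default_rng(config.seed)
    n = config.n

    band_idx = rng.choice(len(config.age_bands), size=n, p=np.asarray(config.age_band_probs))
    lows = np.array([b[0] for b in config.age_bands])
    highs = np.array([b[1] for b in config.age_bands])
    ages = lows[band_idx] + rng.integers(
        0, highs[band_idx] - lows[band_idx] + 1, size=n
    )
    male = rng.random(n) < config.p_male
    smoker = rng.random(n) < config.p_smoker
    pack_years = np.where(
        smoker,
        np.exp(rng.normal(config.log_pack_years_mu, config.log_pack_years_sigma, size=n)),
        0.0,
    )
    cat_idx = rng.choice(len(config.bmi_categories), size=n, p=np.asarray(config.bmi_category_probs))
    cat_lo = np.array([c[0] for c in config.bmi_categories])
    cat_hi = np.array([c[1] for c in config.bmi_categories])
    bmi = cat_lo[cat_idx] + rng.random(n) * (cat_hi[cat_idx] - cat_lo[cat_idx])
    diabetes = rng.random(n) < config.p_diabetes
    fh = rng.random(n) < config.p_family_history
    fdr = np.where(fh, np.where(rng.random(n) < config.p_fdr_ge2_given_fh, 2, 1), 0)

    lp = (
        intercept
        + np.asarray(config.age_band_lor)[band_idx]
        + config.male_lor * male
        + config.smoker_lor * smoker
        + np.asarray(config.bmi_lor)[cat_idx]
        + config.diabetes_lor * diabetes
        + config.family_history_lor * fh
    )
    outcome_can = rng.random(n) < 1.0 / (1.0 + np.exp(-lp))

    width = len(str(n))
    records = tuple(
        SubjectRecord(
            subject_id=f"S{i:0{width}d}",
            age=int(ages[i]),
            sex=MALE if male[i] else FEMALE,
            smoker=bool(smoker[i]),
            pack_years=float(pack_years[i]),
            bmi=float(bmi[i]),
            diabetes=bool(diabetes[i]),
            fdr_crc_count=int(fdr[i]),
            outcome=CAN if outcome_can[i] else NEGATIVE,
        )
        for i in range(n)
    )
    cohort = Cohort(records=records, provenance=f"synthetic(seed={config.seed}, n={n})")

    realized = {
        "prevalence": float(outcome_can.mean()),
        "p_male": float(male.mean()),
        "p_smoker": float(smoker.mean()),
        "p_diabetes": float(diabetes.mean()),
        "p_family_history": float(fh.mean()),
    }
    for k, (lo, hi) in enumerate(config.age_bands):
        realized[f"p_age_{lo}_{hi}"] = float((band_idx == k).mean())
    for k, (lo, hi) in enumerate(config.bmi_categories):
        realized[f"p_bmi_cat{k}"] = float((cat_idx == k).mean())
    report = GeneratorReport(n=n, seed=config.seed, intercept=intercept, realized=realized)
    return cohort, report


def expected_stratum_fraction(config: GeneratorConfig, definition: ScoreDefinition) -> float:
    """Exact P(high risk) under the generator's distribution for one score.

    Enumerates integer ages (uniform within band), the discrete factors, the
    pack-year threshold crossing (log-normal tail) and the BMI threshold
    position inside each uniform category — an analytic oracle for the
    high-risk proportion of large simulated cohorts.
    """
    # P(pack-years item scores | smoker): log-normal upper tail.
    if definition.smoking_rule[0] == SMOKE_PACK_YEARS_GT:
        thr = definition.smoking_rule[1]
        zed = (_LN(thr) - config.log_pack_years_mu) / config.log_pack_years_sigma
        p_py_hit_smoker = 0.5 * math.erfc(zed / math.sqrt(2))
    else:
        p_py_hit_smoker = 0.0

    def p_bmi_hit(ci: int) -> float:
        if definition.bmi_rule is None:
            return 0.0
        thr, _cmp, _pts = definition.bmi_rule  # continuous uniform: >= vs > identical
        lo, hi = config.bmi_categories[ci]
        if thr <= lo:
            return 1.0
        if thr >= hi:
            return 0.0
        return (hi - thr) / (hi - lo)

    fdr_probs = (
        (0, 1.0 - config.p_family_history),
        (1, config.p_family_history * (1.0 - config.p_fdr_ge2_given_fh)),
        (2, config.p_family_history * config.p_fdr_ge2_given_fh),
    )

    total = 0.0
    for bi, pb in enumerate(config.age_band_probs):
        lo_a, hi_a = config.age_bands[bi]
        for age in range(lo_a, hi_a + 1):
            pa = pb / (hi_a - lo_a + 1)
            base_age = definition.age_points(age)
            for male, pm in ((True, config.p_male), (False, 1 - config.p_male)):
                for smoker, ps in ((True, config.p_smoker), (False, 1 - config.p_smoker)):
                    if definition.smoking_rule[0] == SMOKE_EVER:
                        smoke_opts = (((definition.smoking_rule[1] if smoker else 0), 1.0),)
                    else:
                        p_hit = p_py_hit_smoker if smoker else 0.0
                        smoke_opts = (
                            (definition.smoking_rule[2], p_hit),
                            (0, 1.0 - p_hit),
                        )
                    for ci, pc in enumerate(config.bmi_category_probs):
                        ph = p_bmi_hit(ci)
                        bmi_opts = (
                            ((definition.bmi_rule[2] if definition.bmi_rule else 0), ph),
                            (0, 1.0 - ph),
                        )
                        for diab, pd_ in ((True, config.p_diabetes), (False, 1 - config.p_diabetes)):
                            for fdr, pf in fdr_probs:
                                base = (
                                    base_age
                                    + (definition.male_points if male else 0)
                                    + definition.family_history_points(fdr)
                                    + (definition.diabetes_points if diab else 0)
                                )
                                for s_pts, psmk in smoke_opts:
                                    if psmk == 0.0:
                                        continue
                                    for b_pts, pbmi in bmi_opts:
                                        if pbmi == 0.0:
                                            continue
                                        if base + s_pts + b_pts >= definition.cutoff:
                                            total += pa * pm * ps * pc * pd_ * pf * psmk * pbmi
    return total
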