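"""Validation statistics for risk-score stratification.

Implements the full external-validation toolkit for a binary-outcome
screening score: stratum detection rates and the high-risk rate with exact
Clopper-Pearson 95% confidence intervals, relative risk with the Katz
log-method interval, the unadjusted Pearson chi-square test, diagnostic
accuracy (sensitivity / specificity / PPV / NPV), the tie-corrected
concordance statistic (c-statistic) with DeLong variance, the binary net
reclassification improvement (NRI) with the Pencina z-test, and the
colonoscopy resource load (number needed to scope, NNS).

Display rounding is half-up to 2 decimals for percentages and ratios and
half-up to integer for NNS; all internal computation keeps full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .cohort import Cohort, CAN
from .scores import ScoredSubject, HIGH, NON_HIGH

__all__ = [
    "TwoByTwo", "EstimateWithCI", "ReclassTable", "NriResult", "StatsError",
    "round_half_up", "clopper_pearson",
    "make_two_by_two", "detection_rates", "high_risk_rate", "relative_risk",
    "pearson_chi2", "diagnostic_metrics", "c_statistic",
    "build_reclass_table", "nri", "format_nri_ci_published_style",
    "resource_load", "nns_without_score", "stratified_detection",
]


class StatsError(Exception):
    """A statistic is undefined for the given counts."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (0.5 -> 1), as used for all displayed values."""
    q = Decimal(1).scaleb(-ndigits)
    v = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(v) if ndigits > 0 else float(int(v))


@dataclass(frozen=True)
class TwoByTwo:
    """Stratum x outcome contingency counts for one score on one cohort.

    ``a``: CAN & high risk, ``b``: non-CAN & high, ``c``: CAN & non-high,
    ``d``: non-CAN & non-high.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n_high(self) -> int:
        return self.a + self.b

    @property
    def n_non_high(self) -> int:
        return self.c + self.d

    @property
    def n_can(self) -> int:
        return self.a + self.c

    @property
    def n_negative(self) -> int:
        return self.b + self.d

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "TwoByTwo":
        """Exchange the two strata (high <-> non-high)."""
        return TwoByTwo(a=self.c, b=self.d, c=self.a, d=self.b)


@dataclass(frozen=True)
class EstimateWithCI:
    """Point estimate with a confidence interval and its method label."""

    point: float
    lo: float
    hi: float
    level: float = 0.95
    method: str = ""

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        return (
            round_half_up(self.point, ndigits),
            round_half_up(self.lo, ndigits),
            round_half_up(self.hi, ndigits),
        )


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI for a proportion, as (lo, hi) on the [0, 1] scale."""
    if n <= 0:
        raise StatsError("Clopper-Pearson interval undefined for n = 0")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="beta")
    return float(lo), float(hi)


def _pct_estimate(k: int, n: int, level: float, label: str) -> EstimateWithCI:
    lo, hi = clopper_pearson(k, n, level)
    return EstimateWithCI(
        point=100.0 * k / n, lo=100.0 * lo, hi=100.0 * hi,
        level=level, method=f"{label}; Clopper-Pearson exact CI",
    )


def make_two_by_two(
    scored: Sequence[ScoredSubject], outcomes: Mapping[str, Optional[str]]
) -> TwoByTwo:
    """Cross-tabulate scored subjects against their colonoscopy outcomes."""
    a = b = c = d = 0
    for s in scored:
        outcome = outcomes.get(s.subject_id)
        if outcome is None:
            raise StatsError(f"outcome missing for subject {s.subject_id!r}")
        is_can = outcome == CAN
        if s.stratum == HIGH:
            a, b = (a + 1, b) if is_can else (a, b + 1)
        else:
            c, d = (c + 1, d) if is_can else (c, d + 1)
    return TwoByTwo(a=a, b=b, c=c, d=d)


def detection_rates(t: TwoByTwo, level: float = 0.95) -> dict[str, EstimateWithCI]:
    """CAN detection rate per stratum, in percent with exact CIs."""
    out: dict[str, EstimateWithCI] = {}
    for key, k, n in ((HIGH, t.a, t.n_high), (NON_HIGH, t.c, t.n_non_high)):
        if n == 0:
            raise StatsError(f"detection rate undefined: empty {key} stratum")
        out[key] = _pct_estimate(k, n, level, "detection rate")
    return out


def high_risk_rate(t: TwoByTwo, n: Optional[int] = None, level: float = 0.95) -> EstimateWithCI:
    """Fraction of the cohort classified high-risk, percent with exact CI."""
    total = t.n if n is None else n
    if total <= 0:
        raise StatsError("high-risk rate undefined for empty cohort")
    return _pct_estimate(t.n_high, total, level, "high-risk rate")


def relative_risk(t: TwoByTwo, level: float = 0.95) -> EstimateWithCI:
    """Detection-rate ratio, high vs non-high stratum, with the Katz log CI.

    CI: exp(ln RR +/- z * sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))).  With exactly
    one zero event cell the point estimate (0 or inf) is returned with an
    unbounded interval and a flagging method label; both cells zero raises.
    """
    if t.n_high == 0 or t.n_non_high == 0:
        raise StatsError("relative risk undefined: empty stratum")
    if t.a == 0 and t.c == 0:
        raise StatsError("relative risk undefined: no events in either stratum")
    if t.a == 0 or t.c == 0:
        point = 0.0 if t.a == 0 else math.inf
        return EstimateWithCI(
            point=point, lo=0.0, hi=math.inf, level=level,
            method="risk ratio; CI unbounded (zero event cell)",
        )
    rr = (t.a / t.n_high) / (t.c / t.n_non_high)
    z = sps.norm.ppf(0.5 + level / 2)
    se = math.sqrt(1 / t.a - 1 / t.n_high + 1 / t.c - 1 / t.n_non_high)
    return EstimateWithCI(
        point=rr, lo=rr * math.exp(-z * se), hi=rr * math.exp(z * se),
        level=level, method="risk ratio; Katz log CI",
    )


def pearson_chi2(t: TwoByTwo) -> tuple[float, float]:
    """Unadjusted Pearson chi-square (1 df, no continuity correction)."""
    if min(t.n_high, t.n_non_high, t.n_can, t.n_negative) == 0:
        raise StatsError("chi-square undefined: zero margin")
    stat, p, _, _ = sps.chi2_contingency(
        [[t.a, t.b], [t.c, t.d]], correction=False
    )
    return float(stat), float(p)


def diagnostic_metrics(t: TwoByTwo, level: float = 0.95) -> dict[str, EstimateWithCI]:
    """Sensitivity, specificity, PPV, NPV (percent) with exact CIs.

    High-risk classification is treated as the positive test; CAN is the
    condition.  Note detection-rate(high) == PPV by construction.
    """
    cells = {
        "sensitivity": (t.a, t.n_can),
        "specificity": (t.d, t.n_negative),
        "ppv": (t.a, t.n_high),
        "npv": (t.d, t.n_non_high),
    }
    out: dict[str, EstimateWithCI] = {}
    for name, (k, n) in cells.items():
        if n == 0:
            raise StatsError(f"{name} undefined: zero denominator")
        out[name] = _pct_estimate(k, n, level, name)
    return out


# -- concordance statistic -------------------------------------------------

def _c_point(case_scores: np.ndarray, control_scores: np.ndarray) -> float:
    # Mann-Whitney form via midranks: ties count one half.
    m, n = len(case_scores), len(control_scores)
    ranks = sps.rankdata(np.concatenate([case_scores, control_scores]))
    return (ranks[:m].sum() - m * (m + 1) / 2) / (m * n)


def _delong_variance(case_scores: np.ndarray, control_scores: np.ndarray) -> float:
    m, n = len(case_scores), len(control_scores)
    # Structural components: per-case placement among controls and vice versa.
    v10 = np.empty(m)
    for i, x in enumerate(case_scores):
        v10[i] = ((control_scores < x).sum() + 0.5 * (control_scores == x).sum()) / n
    v01 = np.empty(n)
    for j, y in enumerate(control_scores):
        v01[j] = ((case_scores > y).sum() + 0.5 * (case_scores == y).sum()) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def c_statistic(
    scores: Sequence[float], outcomes: Sequence[bool], level: float = 0.95
) -> EstimateWithCI:
    """Tie-corrected concordance statistic with a DeLong-variance CI.

    c = P(score_case > score_control) + 0.5 * P(tie), the AUC of the
    discrete score; computed from midranks, identical to brute-force pair
    enumeration.  Requires at least one case and one control; the CI is
    clipped to [0, 1].
    """
    scores_arr = np.asarray(scores, dtype=float)
    mask = np.asarray(outcomes, dtype=bool)
    if scores_arr.shape != mask.shape:
        raise ValueError("scores and outcomes must have the same length")
    cases, controls = scores_arr[mask], scores_arr[~mask]
    if len(cases) == 0 or len(controls) == 0:
        raise StatsError("c-statistic undefined: single outcome class")
    point = _c_point(cases, controls)
    var = _delong_variance(cases, controls)
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(var)
    return EstimateWithCI(
        point=point, lo=max(0.0, point - half), hi=min(1.0, point + half),
        level=level, method="c-statistic (midrank); DeLong CI",
    )


# -- reclassification ------------------------------------------------------

@dataclass(frozen=True)
class ReclassTable:
    """Paired high/non-high classifications of two scores, split by outcome.

    "up" means comparator non-high reclassified high by the new score;
    "down" the reverse.  Prefix ``e_`` = events (CAN), ``ne_`` = non-events.
    """

    comparator: str
    new_score: str
    e_stay_high: int
    e_up: int
    e_down: int
    e_stay_non: int
    ne_stay_high: int
    ne_up: int
    ne_down: int
    ne_stay_non: int

    @property
    def n_events(self) -> int:
        return self.e_stay_high + self.e_up + self.e_down + self.e_stay_non

    @property
    def n_nonevents(self) -> int:
        return self.ne_stay_high + self.ne_up + self.ne_down + self.ne_stay_non

    def reclassified_percent(self) -> dict[str, float]:
        """Off-diagonal share of each (outcome x new-stratum) row, percent."""
        rows = {
            "events_high": (self.e_up, self.e_stay_high + self.e_up),
            "events_non_high": (self.e_down, self.e_down + self.e_stay_non),
            "nonevents_high": (self.ne_up, self.ne_stay_high + self.ne_up),
            "nonevents_non_high": (self.ne_down, self.ne_down + self.ne_stay_non),
        }
        return {
            k: (100.0 * num / den if den else math.nan)
            for k, (num, den) in rows.items()
        }


def build_reclass_table(
    ref: Mapping[str, str],
    new: Mapping[str, str],
    outcomes: Mapping[str, Optional[str]],
    comparator: str = "comparator",
    new_score: str = "new",
) -> ReclassTable:
    """Cross the comparator's strata with the new score's, split by outcome."""
    if set(ref) != set(new):
        raise StatsError("subject sets differ between the two scorings")
    cells = {k: 0 for k in (
        "e_stay_high", "e_up", "e_down", "e_stay_non",
        "ne_stay_high", "ne_up", "ne_down", "ne_stay_non",
    )}
    for sid, ref_stratum in ref.items():
        outcome = outcomes.get(sid)
        if outcome is None:
            raise StatsError(f"outcome missing for subject {sid!r}")
        prefix = "e" if outcome == CAN else "ne"
        new_stratum = new[sid]
        if ref_stratum == HIGH and new_stratum == HIGH:
            cells[f"{prefix}_stay_high"] += 1
        elif ref_stratum == NON_HIGH and new_stratum == HIGH:
            cells[f"{prefix}_up"] += 1
        elif ref_stratum == HIGH and new_stratum == NON_HIGH:
            cells[f"{prefix}_down"] += 1
        else:
            cells[f"{prefix}_stay_non"] += 1
    return ReclassTable(comparator=comparator, new_score=new_score, **cells)


@dataclass(frozen=True)
class NriResult:
    """Binary NRI (percent) with asymptotic CI, z and two-sided p."""

    estimate: EstimateWithCI
    z: float
    p: float
    se_percent: float
    event_component: float = 0.0
    nonevent_component: float = 0.0


def nri(rt: ReclassTable, level: float = 0.95) -> NriResult:
    """Binary net reclassification improvement with the Pencina z-test.

    NRI = (up_e - down_e)/n_e + (down_ne - up_ne)/n_ne, reported in percent.
    Variance of the z statistic: (up_e + down_e)/n_e^2 +
    (up_ne + down_ne)/n_ne^2 — the original paired-proportions form, which
    also reproduces published intervals for this validation design.  When no
    subject is reclassified in either class the SE is 0 and p is undefined
    (NaN); the degenerate comparison of a score with itself lands here.
    """
    n_e, n_ne = rt.n_events, rt.n_nonevents
    if n_e == 0 or n_ne == 0:
        raise StatsError("NRI undefined: empty outcome class")
    ev = (rt.e_up - rt.e_down) / n_e
    ne = (rt.ne_down - rt.ne_up) / n_ne
    est = ev + ne
    var = (rt.e_up + rt.e_down) / n_e**2 + (rt.ne_up + rt.ne_down) / n_ne**2
    se = math.sqrt(var)
    zcrit = sps.norm.ppf(0.5 + level / 2)
    if se == 0.0:
        z = math.nan if est == 0 else math.copysign(math.inf, est)
        p = math.nan
        lo = hi = est
    else:
        z = est / se
        p = 2 * float(sps.norm.sf(abs(z)))
        lo, hi = est - zcrit * se, est + zcrit * se
    return NriResult(
        estimate=EstimateWithCI(
            point=100 * est, lo=100 * lo, hi=100 * hi, level=level,
            method="binary NRI; Pencina asymptotic z",
        ),
        z=z, p=p, se_percent=100 * se,
        event_component=100 * ev, nonevent_component=100 * ne,
    )


def format_nri_ci_published_style(result: NriResult) -> tuple[float, float]:
    """CI bounds under the 2-decimal quoting convention of validation reports:
    the NRI and the half-width (z * SE, with SE% first rounded to 2 dp) are
    each rounded to 2 decimals before the bounds are formed.  Matches how
    such intervals are typically quoted; full-precision bounds live in
    ``result.estimate``.
    """
    zcrit = sps.norm.ppf(0.5 + result.estimate.level / 2)
    point = round_half_up(result.estimate.point, 2)
    half = round_half_up(zcrit * round_half_up(result.se_percent, 2), 2)
    return (round_half_up(point - half, 2), round_half_up(point + half, 2))


# -- resource load ---------------------------------------------------------

def resource_load(t: TwoByTwo, level: float = 0.95) -> EstimateWithCI:
    """Number needed to scope: colonoscopies per CAN detected in the
    high-risk stratum, (a+b)/a rounded half-up to integer.

    CI bounds invert the exact Clopper-Pearson PPV interval (then round
    half-up); the method label records this since published reports do not
    always state their NNS interval construction.
    """
    if t.n_high == 0:
        raise StatsError("NNS undefined: empty high-risk stratum")
    if t.a == 0:
        raise StatsError("NNS infinite: no CAN detected in the high-risk stratum")
    lo_p, hi_p = clopper_pearson(t.a, t.n_high, level)
    return EstimateWithCI(
        point=round_half_up(t.n_high / t.a),
        lo=round_half_up(1.0 / hi_p),
        hi=round_half_up(1.0 / lo_p),
        level=level, method="NNS; inverse Clopper-Pearson PPV CI, half-up",
    )


def nns_without_score(n: int, n_can: int, level: float = 0.95) -> EstimateWithCI:
    """Baseline resource load when every subject is scoped: N per CAN."""
    if n_can == 0:
        raise StatsError("NNS infinite: no CAN in cohort")
    lo_p, hi_p = clopper_pearson(n_can, n, level)
    return EstimateWithCI(
        point=round_half_up(n / n_can),
        lo=round_half_up(1.0 / hi_p),
        hi=round_half_up(1.0 / lo_p),
        level=level, method="NNS; inverse Clopper-Pearson CI, half-up",
    )


# -- detection by sex and age band ----------------------------------------

def stratified_detection(
    cohort: Cohort,
    bands: Sequence[tuple[int, int]] = ((50, 54), (55, 59), (60, 64), (65, 69), (70, 74)),
    level: float = 0.95,
) -> pd.DataFrame:
    """CAN detection rate per sex x age-band cell with exact CIs.

    ``bands`` must partition [50, 74] into closed integer intervals.  Empty
    cells get NaN rates flagged ``defined = False``.  Subjects outside the
    bands or without an outcome raise.
    """
    srt = sorted(bands)
    if srt[0][0] != 50 or srt[-1][1] != 74 or any(
        b[0] != a[1] + 1 for a, b in zip(srt, srt[1:])
    ):
        raise ValueError("bands must partition [50, 74]")

    rows = []
    for sex in ("male", "female"):
        for lo, hi in srt:
            members = [r for r in cohort if r.sex == sex and lo <= r.age <= hi]
            if any(r.outcome is None for r in members):
                raise StatsError("outcome missing inside a stratification cell")
            n = len(members)
            k = sum(r.outcome == CAN for r in members)
            if n == 0:
                rows.append({
                    "sex": sex, "band": f"{lo}-{hi}", "n": 0, "n_can": 0,
                    "rate_pct": math.nan, "lo_pct": math.nan,
                    "hi_pct": math.nan, "defined": False,
                })
            else:
                ci_lo, ci_hi = clopper_pearson(k, n, level)
                rows.append({
                    "sex": sex, "band": f"{lo}-{hi}", "n": n, "n_can": k,
                    "rate_pct": 100 * k / n, "lo_pct": 100 * ci_lo,
                    "hi_pct": 100 * ci_hi, "defined": True,
                })
    return pd.DataFrame(rows)
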