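"""The five Asia-Pacific colorectal-screening risk scores as declarative rules.

Each scoring system sums points over age band, sex, family history of CRC in
first-degree relatives, smoking and (in the modified versions) BMI and
diabetes, then classifies a subject high-risk when the total meets the
published cut-off.  Points are stored internally in half-point integer
units (value x 2) so the 8-point system's 0.5 and 3.5 items are exact and
score totals are order-comparable without floating point — exact ties
matter for the concordance statistic.

Boundary conventions follow the published algorithms verbatim: BMI uses
">= 25" (CNP, KCS) and ">= 23" (Modified APCS) but strictly "> 22.5"
(8-point); the 8-point smoking item is strictly "> 18.5 pack-years"; its
family-history item needs >= 2 affected first-degree relatives where the
other four systems trigger on any.  Subjects aged 71-74 score the top
printed age band where the published bands stop at 70 (CNP, Modified APCS),
matching the validation study's convention; for those two systems ages
below 50 have no published band and raise rather than silently scoring 0.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

from .cohort import Cohort, SubjectRecord, MALE, CAN

__all__ = [
    "APCS", "CNP", "KCS", "MODIFIED_APCS", "EIGHT_POINT", "SCORE_NAMES",
    "ScoreDefinition", "ScoredSubject", "StratificationSummary",
    "ScoringError", "builtin_definitions", "get_definition",
    "compute_score", "apply_score", "enumerate_max_score",
    "definition_to_dict", "definition_from_dict",
]

APCS = "APCS"
CNP = "CNP"
KCS = "KCS"
MODIFIED_APCS = "Modified APCS"
EIGHT_POINT = "8-point"
SCORE_NAMES = (APCS, CNP, KCS, MODIFIED_APCS, EIGHT_POINT)

_ALIASES = {
    "apcs": APCS, "cnp": CNP, "kcs": KCS,
    "modified apcs": MODIFIED_APCS, "modified_apcs": MODIFIED_APCS,
    "modified-apcs": MODIFIED_APCS, "modapcs": MODIFIED_APCS,
    "8-point": EIGHT_POINT, "8point": EIGHT_POINT, "eight_point": EIGHT_POINT,
    "eight-point": EIGHT_POINT, "eightpoint": EIGHT_POINT,
}

FH_ANY = "any_first_degree_relative"
FH_GE2 = "two_or_more_first_degree_relatives"
SMOKE_EVER = "ever_smoker"
SMOKE_PACK_YEARS_GT = "pack_years_greater_than"

HIGH = "high"
NON_HIGH = "non_high"


class ScoringError(Exception):
    """A subject cannot be scored under a given definition."""


@dataclass(frozen=True)
class ScoreDefinition:
    """Declarative point-assignment rules for one scoring system.

    All point fields are half-point integer units.  ``age_bands`` are closed
    integer intervals ``(lo, hi, points)`` and must not overlap; an age in
    no band is a :class:`ScoringError`.  ``smoking_rule`` is
    ``(SMOKE_EVER, points)`` or ``(SMOKE_PACK_YEARS_GT, threshold, points)``;
    ``bmi_rule`` is ``None`` or ``(threshold, ">="|">", points)``;
    ``family_history_rule`` is ``(FH_ANY|FH_GE2, points)``.
    """

    name: str
    age_bands: tuple[tuple[int, int, int], ...]
    male_points: int
    family_history_rule: tuple[str, int]
    smoking_rule: tuple
    cutoff: int
    max_points: int
    bmi_rule: Optional[tuple[float, str, int]] = None
    diabetes_points: int = 0

    def __post_init__(self) -> None:
        bands = sorted(self.age_bands)
        for (lo1, hi1, _), (lo2, _hi2, _2) in zip(bands, bands[1:]):
            if lo2 <= hi1:
                raise ValueError(f"{self.name}: overlapping age bands")
        for lo, hi, _ in bands:
            if lo > hi:
                raise ValueError(f"{self.name}: empty age band ({lo}, {hi})")
        if self.cutoff > self.max_points:
            raise ValueError(f"{self.name}: cutoff exceeds max_points")
        if enumerate_max_score(self) != self.max_points:
            raise ValueError(
                f"{self.name}: declared max_points {self.max_points} != "
                f"enumerated maximum {enumerate_max_score(self)}"
            )

    # -- component points (half-units) ------------------------------------
    def age_points(self, age: int) -> int:
        for lo, hi, pts in self.age_bands:
            if lo <= age <= hi:
                return pts
        raise ScoringError(f"{self.name}: age {age} falls in no scoring band")

    def sex_points(self, sex: str) -> int:
        return self.male_points if sex == MALE else 0

    def family_history_points(self, fdr_crc_count: int) -> int:
        kind, pts = self.family_history_rule
        needed = 1 if kind == FH_ANY else 2
        return pts if fdr_crc_count >= needed else 0

    def smoking_points(self, smoker: bool, pack_years: Optional[float]) -> int:
        if self.smoking_rule[0] == SMOKE_EVER:
            return self.smoking_rule[1] if smoker else 0
        _, threshold, pts = self.smoking_rule
        if pack_years is None:
            raise ScoringError(
                f"{self.name}: pack_years is required for the pack-year smoking item"
            )
        return pts if pack_years > threshold else 0

    def bmi_points(self, bmi: float) -> int:
        if self.bmi_rule is None:
            return 0
        threshold, cmp_, pts = self.bmi_rule
        hit = bmi >= threshold if cmp_ == ">=" else bmi > threshold
        return pts if hit else 0


@dataclass(frozen=True)
class ScoredSubject:
    """A subject's total score (half-units) and risk stratum under one system."""

    subject_id: str
    score: int
    stratum: str

    @property
    def score_points(self) -> float:
        """Score on the published scale (points, possibly x.5)."""
        return self.score / 2.0


@dataclass(frozen=True)
class StratificationSummary:
    score_name: str
    n_high: int
    n_non_high: int
    can_high: int
    can_non_high: int
    n_outcome_missing: int = 0

    @property
    def n(self) -> int:
        return self.n_high + self.n_non_high


def _halves(points: float) -> int:
    h = points * 2
    if abs(h - round(h)) > 1e-9:
        raise ValueError(f"points {points} is not a multiple of 0.5")
    return int(round(h))


def builtin_definitions() -> tuple[ScoreDefinition, ...]:
    """The five published scoring systems with their validated cut-offs.

    Maxima (points): APCS 7, CNP 6, KCS 8, Modified APCS 6, 8-point 8;
    cut-offs >= 4, >= 3, >= 4, >= 3, >= 5 respectively.
    """
    apcs = ScoreDefinition(
        name=APCS,
        age_bands=((18, 49, 0), (50, 69, _halves(2)), (70, 120, _halves(3))),
        male_points=_halves(1),
        family_history_rule=(FH_ANY, _halves(2)),
        smoking_rule=(SMOKE_EVER, _halves(1)),
        cutoff=_halves(4),
        max_points=_halves(7),
    )
    # Published bands stop at 70; 71-74 are scored as the top band per the
    # validation convention.  No published band below 50.
    cnp = ScoreDefinition(
        name=CNP,
        age_bands=((50, 55, 0), (56, 70, _halves(1)), (71, 74, _halves(1))),
        male_points=_halves(1),
        family_history_rule=(FH_ANY, _halves(1)),
        smoking_rule=(SMOKE_EVER, _halves(1)),
        bmi_rule=(25.0, ">=", _halves(1)),
        diabetes_points=_halves(1),
        cutoff=_halves(3),
        max_points=_halves(6),
    )
    kcs = ScoreDefinition(
        name=KCS,
        age_bands=((18, 49, 0), (50, 69, _halves(2)), (70, 120, _halves(4))),
        male_points=_halves(1),
        family_history_rule=(FH_ANY, _halves(1)),
        smoking_rule=(SMOKE_EVER, _halves(1)),
        bmi_rule=(25.0, ">=", _halves(1)),
        cutoff=_halves(4),
        max_points=_halves(8),
    )
    modified_apcs = ScoreDefinition(
        name=MODIFIED_APCS,
        age_bands=((50, 54, 0), (55, 64, _halves(1)), (65, 70, _halves(2)), (71, 74, _halves(2))),
        male_points=_halves(1),
        family_history_rule=(FH_ANY, _halves(1)),
        smoking_rule=(SMOKE_EVER, _halves(1)),
        bmi_rule=(23.0, ">=", _halves(1)),
        cutoff=_halves(3),
        max_points=_halves(6),
    )
    eight_point = ScoreDefinition(
        name=EIGHT_POINT,
        age_bands=((40, 49, 0), (50, 59, _halves(2)), (60, 69, _halves(3)), (70, 120, _halves(3.5))),
        male_points=_halves(1),
        family_history_rule=(FH_GE2, _halves(2)),
        smoking_rule=(SMOKE_PACK_YEARS_GT, 18.5, _halves(1)),
        bmi_rule=(22.5, ">", _halves(0.5)),
        cutoff=_halves(5),
        max_points=_halves(8),
    )
    return (apcs, cnp, kcs, modified_apcs, eight_point)


def get_definition(name: str) -> ScoreDefinition:
    """Look up a built-in definition by name (case/punctuation tolerant)."""
    key = name.strip().lower()
    canonical = _ALIASES.get(key)
    if canonical is None:
        raise KeyError(f"unknown scoring system {name!r}; known: {', '.join(SCORE_NAMES)}")
    for d in builtin_definitions():
        if d.name == canonical:
            return d
    raise AssertionError("unreachable")


def enumerate_max_score(definition: ScoreDefinition) -> int:
    """Maximum attainable score (half-units) by exhaustive factor-grid search."""
    ages = [lo for lo, _, _ in definition.age_bands]
    thr = definition.smoking_rule[1] if definition.smoking_rule[0] == SMOKE_PACK_YEARS_GT else 0
    pack_years_opts = [0.0, float(thr) + 1.0]
    bmis = [15.0]
    if definition.bmi_rule is not None:
        bmis.append(definition.bmi_rule[0] + 1.0)
    best = 0
    for age, male, smoker, py, bmi, diab, fdr in itertools.product(
        ages, (False, True), (False, True), pack_years_opts, bmis, (False, True), (0, 1, 2)
    ):
        total = (
            definition.age_points(age)
            + (definition.male_points if male else 0)
            + definition.family_history_points(fdr)
            + definition.smoking_points(smoker, py)
            + definition.bmi_points(bmi)
            + (definition.diabetes_points if diab else 0)
        )
        best = max(best, total)
    return best


def compute_score(subject: SubjectRecord, definition: ScoreDefinition) -> ScoredSubject:
    """Total a subject's points under one system and assign the stratum.

    Raises :class:`ScoringError` when the age falls in no band, a required
    factor is missing, or (8-point only) pack_years is absent.
    """
    for name in ("smoker", "bmi", "diabetes", "fdr_crc_count"):
        if getattr(subject, name) is None:
            raise ScoringError(
                f"{definition.name}: subject {subject.subject_id!r} is missing {name}"
            )
    try:
        total = (
            definition.age_points(subject.age)
            + definition.sex_points(subject.sex)
            + definition.family_history_points(subject.fdr_crc_count)
            + definition.smoking_points(subject.smoker, subject.pack_years)
            + definition.bmi_points(subject.bmi)
            + (definition.diabetes_points if subject.diabetes else 0)
        )
    except ScoringError as exc:
        raise ScoringError(f"subject {subject.subject_id!r}: {exc}") from None
    stratum = HIGH if total >= definition.cutoff else NON_HIGH
    return ScoredSubject(subject_id=subject.subject_id, score=total, stratum=stratum)


def apply_score(
    cohort: Cohort, definition: ScoreDefinition
) -> tuple[list[ScoredSubject], StratificationSummary]:
    """Score every record and summarise the high / non-high stratification.

    CAN counts in the summary cover records with a known outcome;
    ``n_outcome_missing`` reports the rest.
    """
    scored: list[ScoredSubject] = []
    n_high = n_non = can_high = can_non = missing = 0
    for record in cohort:
        s = compute_score(record, definition)
        scored.append(s)
        if s.stratum == HIGH:
            n_high += 1
        else:
            n_non += 1
        if record.outcome is None:
            missing += 1
        elif record.outcome == CAN:
            if s.stratum == HIGH:
                can_high += 1
            else:
                can_non += 1
    summary = StratificationSummary(
        score_name=definition.name,
        n_high=n_high, n_non_high=n_non,
        can_high=can_high, can_non_high=can_non,
        n_outcome_missing=missing,
    )
    return scored, summary


# -- config-document round-trip (users may define custom systems) ----------

def definition_to_dict(definition: ScoreDefinition) -> dict:
    d = asdict(definition)
    d["age_bands"] = [list(b) for b in definition.age_bands]
    d["family_history_rule"] = list(definition.family_history_rule)
    d["smoking_rule"] = list(definition.smoking_rule)
    if definition.bmi_rule is not None:
        d["bmi_rule"] = list(definition.bmi_rule)
    return d


def definition_from_dict(data: dict) -> ScoreDefinition:
    return ScoreDefinition(
        name=data["name"],
        age_bands=tuple(tuple(b) for b in data["age_bands"]),
        male_points=int(data["male_points"]),
        family_history_rule=tuple(data["family_history_rule"]),
        smoking_rule=tuple(data["smoking_rule"]),
        bmi_rule=tuple(data["bmi_rule"]) if data.get("bmi_rule") else None,
        diabetes_points=int(data.get("diabetes_points", 0)),
        cutoff=int(data["cutoff"]),
        max_points=int(data["max_points"]),
    )


def definitions_to_json(definitions: Sequence[ScoreDefinition]) -> str:
    return json.dumps([definition_to_dict(d) for d in definitions], indent=2)


def definitions_from_json(text: str) -> list[ScoreDefinition]:
    return [definition_from_dict(d) for d in json.loads(text)]
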