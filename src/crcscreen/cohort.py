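"""Subject-level cohort data model, delimited-text I/O and eligibility filtering.

A screening cohort is one row per screened individual carrying the risk
factors the five scoring systems consume (age, sex, smoking, pack-years,
BMI, diabetes, first-degree-relative CRC count) plus the colonoscopy
outcome: colorectal advanced neoplasia (CAN — colorectal cancer, or any
adenoma >= 1 cm, with high-grade dysplasia or tubular-villous histology)
versus negative.  Records awaiting colonoscopy carry a missing outcome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import pandas as pd

__all__ = [
    "MALE", "FEMALE", "CAN", "NEGATIVE", "REQUIRED_COLUMNS",
    "SubjectRecord", "Cohort", "ExclusionLog",
    "CohortError", "CohortFormatError", "CohortRowError",
    "read_cohort", "write_cohort", "filter_eligible", "parse_frame",
]

MALE = "male"
FEMALE = "female"
CAN = "CAN"
NEGATIVE = "negative"

#: Header names required in any cohort file, in canonical write order.
REQUIRED_COLUMNS = (
    "subject_id", "age", "sex", "smoker", "pack_years",
    "bmi", "diabetes", "fdr_crc_count", "outcome",
)

# Documented normalization maps: values are trimmed and lower-cased first.
_SEX_MAP = {"male": MALE, "m": MALE, "female": FEMALE, "f": FEMALE}
_BOOL_MAP = {
    "1": True, "0": False, "yes": True, "no": False,
    "true": True, "false": False,
}
_OUTCOME_MAP = {"can": CAN, "negative": NEGATIVE}
_MISSING_TOKENS = {"", "na", "nan", "none", "null"}


class CohortError(Exception):
    """Base class for cohort I/O and validation failures."""


class CohortFormatError(CohortError):
    """File-level failure: missing column, duplicate ids, unreadable file."""


class CohortRowError(CohortError):
    """One or more data rows failed type/invariant validation.

    ``diagnostics`` is a list of ``(row_number, message)`` pairs where
    ``row_number`` is the 1-based data-row index (header excluded).
    """

    def __init__(self, diagnostics: Sequence[tuple[int, str]]):
        self.diagnostics = list(diagnostics)
        lines = "; ".join(f"row {i}: {m}" for i, m in self.diagnostics[:10])
        more = "" if len(self.diagnostics) <= 10 else f" (+{len(self.diagnostics) - 10} more)"
        super().__init__(f"{len(self.diagnostics)} invalid row(s): {lines}{more}")


def _is_missing(token: str) -> bool:
    return token.strip().lower() in _MISSING_TOKENS


@dataclass(frozen=True)
class SubjectRecord:
    """One screened individual's risk factors and colonoscopy outcome.

    ``pack_years`` may be missing (only the 8-point score needs it);
    ``bmi``/``smoker``/``diabetes``/``fdr_crc_count`` may be missing on raw
    records but are required for eligibility.  ``outcome`` is missing for
    pre-colonoscopy records.
    """

    subject_id: str
    age: int
    sex: str
    smoker: Optional[bool]
    pack_years: Optional[float]
    bmi: Optional[float]
    diabetes: Optional[bool]
    fdr_crc_count: Optional[int]
    outcome: Optional[str]

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        if not isinstance(self.age, int) or isinstance(self.age, bool):
            raise ValueError(f"age must be an integer, got {self.age!r}")
        if not 18 <= self.age <= 120:
            raise ValueError(f"age {self.age} outside [18, 120]")
        if self.sex not in (MALE, FEMALE):
            raise ValueError(f"sex must be {MALE!r} or {FEMALE!r}, got {self.sex!r}")
        if self.pack_years is not None and self.pack_years < 0:
            raise ValueError(f"pack_years {self.pack_years} must be >= 0")
        if self.bmi is not None and not 10 < self.bmi < 80:
            raise ValueError(f"bmi {self.bmi} outside (10, 80)")
        if self.fdr_crc_count is not None and self.fdr_crc_count < 0:
            raise ValueError(f"fdr_crc_count {self.fdr_crc_count} must be >= 0")
        if self.outcome is not None and self.outcome not in (CAN, NEGATIVE):
            raise ValueError(f"outcome must be {CAN!r}/{NEGATIVE!r} or missing, got {self.outcome!r}")

    @property
    def family_history(self) -> Optional[bool]:
        """First-degree relative with CRC (derived from ``fdr_crc_count``)."""
        if self.fdr_crc_count is None:
            return None
        return self.fdr_crc_count >= 1

    @property
    def is_can(self) -> Optional[bool]:
        if self.outcome is None:
            return None
        return self.outcome == CAN


@dataclass(frozen=True)
class Cohort:
    """Ordered collection of :class:`SubjectRecord` with unique ids."""

    records: tuple[SubjectRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[str] = set()
        for r in self.records:
            if r.subject_id in seen:
                raise CohortFormatError(f"duplicate subject_id {r.subject_id!r}")
            seen.add(r.subject_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.records)

    def outcomes(self) -> dict[str, Optional[str]]:
        return {r.subject_id: r.outcome for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        """Canonical tabular form (column order = :data:`REQUIRED_COLUMNS`)."""
        rows = []
        for r in self.records:
            rows.append({
                "subject_id": r.subject_id,
                "age": r.age,
                "sex": r.sex,
                "smoker": _fmt_bool(r.smoker),
                "pack_years": "" if r.pack_years is None else repr(float(r.pack_years)),
                "bmi": "" if r.bmi is None else repr(float(r.bmi)),
                "diabetes": _fmt_bool(r.diabetes),
                "fdr_crc_count": "" if r.fdr_crc_count is None else r.fdr_crc_count,
                "outcome": "" if r.outcome is None else r.outcome,
            })
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def _fmt_bool(v: Optional[bool]) -> str:
    if v is None:
        return ""
    return "1" if v else "0"


def _parse_row(row: pd.Series) -> SubjectRecord:
    def cell(name: str) -> str:
        return str(row[name]).strip()

    def parse_bool(name: str) -> Optional[bool]:
        tok = cell(name)
        if _is_missing(tok):
            return None
        try:
            return _BOOL_MAP[tok.lower()]
        except KeyError:
            raise ValueError(f"column {name!r}: unparseable boolean {tok!r}") from None

    def parse_float(name: str) -> Optional[float]:
        tok = cell(name)
        if _is_missing(tok):
            return None
        try:
            return float(tok)
        except ValueError:
            raise ValueError(f"column {name!r}: unparseable number {tok!r}") from None

    def parse_int(name: str) -> Optional[int]:
        tok = cell(name)
        if _is_missing(tok):
            return None
        try:
            return int(tok)
        except ValueError:
            raise ValueError(f"column {name!r}: unparseable integer {tok!r}") from None

    age = parse_int("age")
    if age is None:
        raise ValueError("column 'age': value is required")
    sex_tok = cell("sex").lower()
    if sex_tok not in _SEX_MAP:
        raise ValueError(f"column 'sex': unparseable value {cell('sex')!r}")
    outcome_tok = cell("outcome")
    outcome = None if _is_missing(outcome_tok) else _OUTCOME_MAP.get(outcome_tok.lower())
    if outcome is None and not _is_missing(outcome_tok):
        raise ValueError(f"column 'outcome': unparseable value {outcome_tok!r}")

    return SubjectRecord(
        subject_id=cell("subject_id"),
        age=age,
        sex=_SEX_MAP[sex_tok],
        smoker=parse_bool("smoker"),
        pack_years=parse_float("pack_years"),
        bmi=parse_float("bmi"),
        diabetes=parse_bool("diabetes"),
        fdr_crc_count=parse_int("fdr_crc_count"),
        outcome=outcome,
    )


def parse_frame(df: pd.DataFrame, provenance: str = "") -> tuple[Cohort, list[tuple[int, str]]]:
    """Validate a string-typed frame row by row.

    Returns the cohort of valid records plus row-indexed diagnostics
    (1-based data-row numbers) for rejected rows.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing required column(s): {', '.join(missing)}")
    records: list[SubjectRecord] = []
    diagnostics: list[tuple[int, str]] = []
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            records.append(_parse_row(row))
        except ValueError as exc:
            diagnostics.append((pos, str(exc)))
    return Cohort(records=tuple(records), provenance=provenance), diagnostics


def read_cohort(path, delimiter: str = ",", on_invalid: str = "raise") -> Cohort:
    """Read a delimited-text cohort (UTF-8, header row required).

    Booleans are accepted as {0,1,yes,no,true,false}, sex as
    {male,female,m,f}, all case-insensitively after trimming; missing cells
    are empty or "NA".  ``on_invalid`` is ``"raise"`` (default; any bad row
    aborts with row-numbered diagnostics) or ``"drop"`` (bad rows are
    discarded silently; use :func:`parse_frame` to inspect them).
    """
    if on_invalid not in ("raise", "drop"):
        raise ValueError("on_invalid must be 'raise' or 'drop'")
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    cohort, diagnostics = parse_frame(df, provenance=str(path))
    if diagnostics and on_invalid == "raise":
        raise CohortRowError(diagnostics)
    return cohort


def write_cohort(cohort: Cohort, path, delimiter: str = ",") -> None:
    """Write in the canonical dialect; round-trips through :func:`read_cohort`."""
    cohort.to_frame().to_csv(path, sep=delimiter, index=False)


@dataclass(frozen=True)
class ExclusionLog:
    """Per-reason exclusion counts from :func:`filter_eligible`.

    Invariant: ``sum(counts.values()) + n_retained == n_input``.
    """

    n_input: int
    n_retained: int
    counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"n_input": self.n_input, "n_retained": self.n_retained,
             "excluded": dict(self.counts)},
            sort_keys=True,
        )

    def format_text(self) -> str:
        lines = [f"input\t{self.n_input}", f"retained\t{self.n_retained}"]
        lines += [f"excluded:{k}\t{v}" for k, v in sorted(self.counts.items())]
        return "\n".join(lines)


def filter_eligible(
    cohort: Cohort, require_pack_years: bool = False
) -> tuple[Cohort, ExclusionLog]:
    """Apply the study eligibility filter: age 50-74, colonoscopy outcome
    present, and complete risk factors (bmi, smoker, diabetes, fdr_crc_count;
    pack_years too when the 8-point score is requested).

    Each excluded record is counted under its first failing reason, checked
    in the order age, outcome, bmi, smoker, diabetes, fdr_crc_count,
    pack_years.  Idempotent: filtering a filtered cohort changes nothing.
    """
    kept: list[SubjectRecord] = []
    counts: dict[str, int] = {}

    def reason_for(r: SubjectRecord) -> Optional[str]:
        if not 50 <= r.age <= 74:
            return "age"
        if r.outcome is None:
            return "outcome"
        for name in ("bmi", "smoker", "diabetes", "fdr_crc_count"):
            if getattr(r, name) is None:
                return name
        if require_pack_years and r.pack_years is None:
            return "pack_years"
        return None

    for r in cohort:
        reason = reason_for(r)
        if reason is None:
            kept.append(r)
        else:
            counts[reason] = counts.get(reason, 0) + 1

    filtered = Cohort(records=tuple(kept), provenance=cohort.provenance)
    log = ExclusionLog(n_input=len(cohort), n_retained=len(kept), counts=counts)
    return filtered, log
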