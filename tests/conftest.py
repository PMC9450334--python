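import numpy as np
import pytest

from crcscreen.cohort import Cohort, SubjectRecord


def make_subject(**overrides) -> SubjectRecord:
    """A valid eligible subject; override any field."""
    base = dict(
        subject_id="S1", age=60, sex="female", smoker=False, pack_years=0.0,
        bmi=22.0, diabetes=False, fdr_crc_count=0, outcome="negative",
    )
    base.update(overrides)
    return SubjectRecord(**base)


@pytest.fixture
def subject_factory():
    return make_subject


@pytest.fixture
def small_cohort():
    """Ten hand-constructed subjects spanning strata and outcomes."""
    rows = [
        # (id, age, sex, smoker, py, bmi, dm, fdr, outcome)
        ("P01", 52, "male", True, 25.0, 26.0, False, 0, "CAN"),
        ("P02", 55, "female", False, 0.0, 21.0, False, 0, "negative"),
        ("P03", 68, "male", True, 10.0, 24.0, True, 1, "CAN"),
        ("P04", 71, "female", False, 0.0, 28.0, False, 0, "negative"),
        ("P05", 50, "male", False, 0.0, 22.0, False, 2, "negative"),
        ("P06", 63, "female", True, 30.0, 23.5, False, 0, "CAN"),
        ("P07", 59, "male", False, 0.0, 19.0, False, 0, "negative"),
        ("P08", 74, "male", True, 40.0, 31.0, True, 1, "CAN"),
        ("P09", 66, "female", False, 0.0, 25.0, False, 0, "negative"),
        ("P10", 57, "female", False, 0.0, 22.4, True, 0, "negative"),
    ]
    records = tuple(
        SubjectRecord(subject_id=i, age=a, sex=s, smoker=sm, pack_years=py,
                      bmi=b, diabetes=dm, fdr_crc_count=f, outcome=o)
        for i, a, s, sm, py, b, dm, f, o in rows
    )
    return Cohort(records=records, provenance="toy")


def brute_force_c(scores, outcomes) -> float:
    """O(n^2) pair-counting oracle for the tie-corrected concordance."""
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=bool)
    cases = scores[outcomes]
    controls = scores[~outcomes]
    wins = (cases[:, None] > controls[None, :]).sum()
    ties = (cases[:, None] == controls[None, :]).sum()
    return (wins + 0.5 * ties) / (len(cases) * len(controls))
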