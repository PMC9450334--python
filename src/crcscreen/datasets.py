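"""Published counts from an urban Chinese screening-programme external validation.

The validation cohort (N = 1804 screening colonoscopies, 112 with colorectal
advanced neoplasia) published its per-score stratum x outcome counts and the
pairwise reclassification cells against the APCS comparator.  Those printed
counts are sufficient inputs for every stratification, accuracy, NRI and
resource-load statistic (the c-statistic alone needs subject-level scores
and is not recomputable from them).  They are transcribed here so the
published results can be recomputed end-to-end from count data.
"""

from __future__ import annotations

from .scores import APCS, CNP, KCS, MODIFIED_APCS, EIGHT_POINT
from .stats import ReclassTable, TwoByTwo

__all__ = [
    "STUDY_N", "STUDY_CAN", "STUDY_TWO_BY_TWO", "STUDY_RECLASS_VS_APCS",
]

#: Eligible subjects in the validation analysis.
STUDY_N = 1804
#: Colorectal advanced neoplasia cases detected (prevalence 6.21%).
STUDY_CAN = 112

#: Stratum x outcome counts per scoring system:
#: a = CAN & high risk, b = negative & high, c = CAN & non-high, d = negative & non-high.
STUDY_TWO_BY_TWO: dict[str, TwoByTwo] = {
    APCS: TwoByTwo(a=82, b=809, c=30, d=883),
    CNP: TwoByTwo(a=81, b=787, c=31, d=905),
    KCS: TwoByTwo(a=92, b=879, c=20, d=813),
    MODIFIED_APCS: TwoByTwo(a=95, b=956, c=17, d=736),
    EIGHT_POINT: TwoByTwo(a=35, b=274, c=77, d=1418),
}

#: Reclassification cells of each modified score against the APCS comparator,
#: split into events (CAN) and non-events.  "up" = APCS non-high -> new high.
STUDY_RECLASS_VS_APCS: dict[str, ReclassTable] = {
    CNP: ReclassTable(
        comparator=APCS, new_score=CNP,
        e_stay_high=73, e_up=8, e_down=9, e_stay_non=22,
        ne_stay_high=655, ne_up=132, ne_down=154, ne_stay_non=751,
    ),
    KCS: ReclassTable(
        comparator=APCS, new_score=KCS,
        e_stay_high=81, e_up=11, e_down=1, e_stay_non=19,
        ne_stay_high=738, ne_up=141, ne_down=71, ne_stay_non=742,
    ),
    MODIFIED_APCS: ReclassTable(
        comparator=APCS, new_score=MODIFIED_APCS,
        e_stay_high=79, e_up=16, e_down=3, e_stay_non=14,
        ne_stay_high=710, ne_up=246, ne_down=99, ne_stay_non=637,
    ),
    EIGHT_POINT: ReclassTable(
        comparator=APCS, new_score=EIGHT_POINT,
        e_stay_high=35, e_up=0, e_down=47, e_stay_non=30,
        ne_stay_high=274, ne_up=0, ne_down=535, ne_stay_non=883,
    ),
}
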