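"""Validation statistics: exact reproduction of the published count-derived
values, agreement with independent oracles, and algebraic invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crcscreen.datasets import (
    STUDY_CAN, STUDY_N, STUDY_RECLASS_VS_APCS, STUDY_TWO_BY_TWO,
)
from crcscreen.scores import (
    APCS, CNP, EIGHT_POINT, KCS, MODIFIED_APCS, HIGH, NON_HIGH,
    ScoredSubject, apply_score, builtin_definitions,
)
from crcscreen.stats import (
    ReclassTable, StatsError, TwoByTwo,
    build_reclass_table, c_statistic, detection_rates, diagnostic_metrics,
    format_nri_ci_published_style, high_risk_rate, make_two_by_two,
    nns_without_score, nri, pearson_chi2, relative_risk, resource_load,
    round_half_up, stratified_detection,
)
from conftest import brute_force_c, make_subject


class TestTwoByTwo:
    def test_margins(self):
        t = STUDY_TWO_BY_TWO[APCS]
        assert (t.n_high, t.n_non_high, t.n_can, t.n) == (891, 913, 112, 1804)

    def test_make_two_by_two_hand_counts(self, small_cohort):
        scored, _ = apply_score(small_cohort, builtin_definitions()[0])
        t = make_two_by_two(scored, small_cohort.outcomes())
        # hand enumeration: APCS scores per subject
        # P01 m52 smoker: 2+1+1=4 H CAN | P02 f55: 2 N | P03 m68 smoker FH: 2+1+1+2=6 H CAN
        # P04 f71: 3 N | P05 m50 FH2: 2+1+2=5 H neg | P06 f63 smoker: 3 N CAN
        # P07 m59: 3 N | P08 m74 smoker FH: 3+1+1+2=7 H CAN | P09 f66: 2 N | P10 f57: 2 N
        assert (t.a, t.b, t.c, t.d) == (3, 1, 1, 5)

    def test_missing_outcome_names_subject(self):
        scored = [ScoredSubject("x", 8, HIGH)]
        with pytest.raises(StatsError, match="'x'"):
            make_two_by_two(scored, {"x": None})

    def test_all_negative_cohort(self):
        scored = [ScoredSubject("a", 8, HIGH), ScoredSubject("b", 2, NON_HIGH)]
        t = make_two_by_two(scored, {"a": "negative", "b": "negative"})
        assert t.a == 0 and t.c == 0 and t.n == 2


class TestRates:
    def test_detection_rates_published(self):
        det = detection_rates(STUDY_TWO_BY_TWO[APCS])
        assert det[HIGH].rounded() == (9.20, 7.39, 11.29)
        assert round_half_up(det[NON_HIGH].point, 2) == 3.29

    def test_zero_events_rate(self):
        det = detection_rates(TwoByTwo(0, 10, 1, 9))
        assert det[HIGH].point == 0.0 and det[HIGH].lo == 0.0

    def test_empty_stratum_raises(self):
        with pytest.raises(StatsError):
            detection_rates(TwoByTwo(1, 1, 0, 0))

    @pytest.mark.parametrize("name,expected", [
        (APCS, 49.39), (CNP, 48.12), (KCS, 53.82),
        (MODIFIED_APCS, 58.26), (EIGHT_POINT, 17.13),
    ])
    def test_high_risk_rates_published(self, name, expected):
        est = high_risk_rate(STUDY_TWO_BY_TWO[name])
        assert round_half_up(est.point, 2) == expected

    def test_high_risk_rate_zero(self):
        assert high_risk_rate(TwoByTwo(0, 0, 5, 5)).point == 0.0

    def test_detection_rate_high_equals_ppv(self):
        for t in STUDY_TWO_BY_TWO.values():
            det = detection_rates(t)[HIGH]
            ppv = diagnostic_metrics(t)["ppv"]
            assert det.point == ppv.point and det.lo == ppv.lo


class TestRelativeRisk:
    @pytest.mark.parametrize("name,expected", [
        (APCS, (2.80, 1.86, 4.21)), (CNP, (2.82, 1.88, 4.22)),
        (KCS, (3.95, 2.46, 6.34)), (MODIFIED_APCS, (4.00, 2.41, 6.65)),
        (EIGHT_POINT, (2.20, 1.50, 3.22)),
    ])
    def test_published_katz_intervals(self, name, expected):
        assert relative_risk(STUDY_TWO_BY_TWO[name]).rounded() == expected

    def test_symmetric_table_gives_unity(self):
        est = relative_risk(TwoByTwo(5, 45, 5, 45))
        assert est.point == pytest.approx(1.0)

    def test_antisymmetry_under_stratum_swap(self):
        t = STUDY_TWO_BY_TWO[KCS]
        fwd, rev = relative_risk(t), relative_risk(t.swapped())
        assert rev.point == pytest.approx(1 / fwd.point)
        assert rev.lo == pytest.approx(1 / fwd.hi)
        assert rev.hi == pytest.approx(1 / fwd.lo)

    def test_zero_cells(self):
        est = relative_risk(TwoByTwo(0, 10, 5, 5))
        assert est.point == 0.0 and "unbounded" in est.method
        with pytest.raises(StatsError):
            relative_risk(TwoByTwo(0, 10, 0, 10))


class TestChiSquare:
    def test_published_tables_all_significant(self):
        for t in STUDY_TWO_BY_TWO.values():
            stat, p = pearson_chi2(t)
            assert p < 0.001 and stat > 0

    def test_independent_table_statistic_zero(self):
        stat, p = pearson_chi2(TwoByTwo(5, 5, 5, 5))
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)
        stat, _ = pearson_chi2(TwoByTwo(2, 8, 4, 16))
        assert stat == pytest.approx(0.0)

    def test_zero_margin_raises(self):
        with pytest.raises(StatsError):
            pearson_chi2(TwoByTwo(0, 5, 0, 5))


PUBLISHED_ACCURACY = {
    APCS: {"sensitivity": (73.21, 64.02, 81.14), "specificity": (52.19, 49.78, 54.59),
           "ppv": (9.20, 7.39, 11.29), "npv": (96.71, 95.34, 97.77)},
    CNP: {"sensitivity": (72.32, 63.07, 80.36), "specificity": (53.49, 51.08, 55.89),
          "ppv": (9.33, 7.48, 11.47), "npv": (96.69, 95.33, 97.74)},
    KCS: {"sensitivity": (82.14, 73.78, 88.74), "specificity": (48.05, 45.64, 50.46),
          "ppv": (9.47, 7.71, 11.49), "npv": (97.60, 96.32, 98.53)},
    MODIFIED_APCS: {"sensitivity": (84.82, 76.81, 90.90), "specificity": (43.50, 41.12, 45.90),
                    "ppv": (9.04, 7.37, 10.94), "npv": (97.74, 96.41, 98.68)},
    EIGHT_POINT: {"sensitivity": (31.25, 22.83, 40.70), "specificity": (83.81, 81.96, 85.53),
                  "ppv": (11.33, 8.02, 15.40), "npv": (94.85, 93.60, 95.91)},
}


class TestDiagnosticAccuracy:
    @pytest.mark.parametrize("name", list(PUBLISHED_ACCURACY))
    def test_published_values_to_two_decimals(self, name):
        got = diagnostic_metrics(STUDY_TWO_BY_TWO[name])
        for metric, expected in PUBLISHED_ACCURACY[name].items():
            assert got[metric].rounded() == expected, (name, metric)

    def test_perfect_classifier(self):
        got = diagnostic_metrics(TwoByTwo(7, 0, 0, 13))
        assert got["sensitivity"].point == 100.0
        assert got["specificity"].point == 100.0

    def test_consistency_identity(self):
        # PPV * n_high == sensitivity * n_can (both equal a, up to scaling)
        for t in STUDY_TWO_BY_TWO.values():
            m = diagnostic_metrics(t)
            assert m["ppv"].point * t.n_high == pytest.approx(
                m["sensitivity"].point * t.n_can
            )
            assert m["npv"].point / 100 * t.n_non_high == pytest.approx(t.d)
            assert m["specificity"].point / 100 * t.n_negative == pytest.approx(t.d)

    def test_ci_bounds_contain_point_and_respect_range(self):
        for t in STUDY_TWO_BY_TWO.values():
            for est in diagnostic_metrics(t).values():
                assert 0 <= est.lo <= est.point <= est.hi <= 100


class TestCStatistic:
    def test_perfect_separation(self):
        est = c_statistic([5, 5, 1, 1], [True, True, False, False])
        assert est.point == 1.0

    def test_all_ties(self):
        est = c_statistic([3] * 10, [True] * 4 + [False] * 6)
        assert est.point == 0.5

    def test_single_class_raises(self):
        with pytest.raises(StatsError):
            c_statistic([1, 2], [True, True])

    def test_matches_brute_force_with_heavy_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(10, 400))
            scores = rng.integers(0, 16, size=n)  # half-unit score scale
            outcomes = rng.random(n) < 0.3
            if outcomes.all() or not outcomes.any():
                continue
            est = c_statistic(scores, outcomes)
            assert est.point == brute_force_c(scores, outcomes)

    def test_delong_ci_contains_point(self):
        rng = np.random.default_rng(0)
        scores = rng.integers(0, 16, size=300)
        outcomes = rng.random(300) < (scores / 20)
        est = c_statistic(scores, outcomes)
        assert 0 <= est.lo <= est.point <= est.hi <= 1


class TestReclassification:
    def test_published_cnp_cells(self):
        rt = STUDY_RECLASS_VS_APCS[CNP]
        assert (rt.e_stay_high, rt.e_up, rt.e_down, rt.e_stay_non) == (73, 8, 9, 22)
        assert rt.n_events == STUDY_CAN and rt.n_nonevents == STUDY_N - STUDY_CAN
        pct = rt.reclassified_percent()
        assert round_half_up(pct["events_high"], 2) == 9.88
        assert round_half_up(pct["events_non_high"], 2) == 29.03
        assert round_half_up(pct["nonevents_high"], 2) == 16.77
        assert round_half_up(pct["nonevents_non_high"], 2) == 17.02

    def test_build_reclass_table_identity_and_flip(self):
        ref = {"a": HIGH, "b": NON_HIGH, "c": HIGH}
        outcomes = {"a": "CAN", "b": "negative", "c": "negative"}
        same = build_reclass_table(ref, ref, outcomes)
        assert same.e_up == same.e_down == same.ne_up == same.ne_down == 0
        flipped = {k: NON_HIGH if v == HIGH else HIGH for k, v in ref.items()}
        rt = build_reclass_table(ref, flipped, outcomes)
        assert rt.e_stay_high == rt.e_stay_non == 0
        assert rt.ne_stay_high == rt.ne_stay_non == 0

    def test_subject_set_mismatch_raises(self):
        with pytest.raises(StatsError):
            build_reclass_table({"a": HIGH}, {"b": HIGH}, {"a": "CAN", "b": "CAN"})

    def test_cells_conserve_class_totals(self):
        for rt in STUDY_RECLASS_VS_APCS.values():
            assert rt.n_events + rt.n_nonevents == STUDY_N


class TestNRI:
    @pytest.mark.parametrize("name,expected_pct,expected_p", [
        (CNP, 0.41, 0.915), (KCS, 4.79, 0.136),
        (MODIFIED_APCS, 2.92, 0.470), (EIGHT_POINT, -10.34, 0.099),
    ])
    def test_published_points_and_p(self, name, expected_pct, expected_p):
        res = nri(STUDY_RECLASS_VS_APCS[name])
        assert round_half_up(res.estimate.point, 2) == expected_pct
        assert round_half_up(res.p, 3) == expected_p

    @pytest.mark.parametrize("name,expected_ci", [
        (CNP, (-7.06, 7.88)), (KCS, (-1.50, 11.08)),
        (MODIFIED_APCS, (-5.00, 10.84)), (EIGHT_POINT, (-22.63, 1.95)),
    ])
    def test_published_intervals_under_quoting_convention(self, name, expected_ci):
        res = nri(STUDY_RECLASS_VS_APCS[name])
        assert format_nri_ci_published_style(res) == expected_ci

    def test_self_comparison_degenerate(self):
        rt = ReclassTable("A", "A", 10, 0, 0, 5, 20, 0, 0, 30)
        res = nri(rt)
        assert res.estimate.point == 0.0 and math.isnan(res.p)

    def test_antisymmetry(self):
        rt = STUDY_RECLASS_VS_APCS[KCS]
        reverse = ReclassTable(
            comparator=rt.new_score, new_score=rt.comparator,
            e_stay_high=rt.e_stay_high, e_up=rt.e_down, e_down=rt.e_up,
            e_stay_non=rt.e_stay_non,
            ne_stay_high=rt.ne_stay_high, ne_up=rt.ne_down,
            ne_down=rt.ne_up, ne_stay_non=rt.ne_stay_non,
        )
        assert nri(reverse).estimate.point == pytest.approx(-nri(rt).estimate.point)

    def test_empty_class_raises(self):
        with pytest.raises(StatsError):
            nri(ReclassTable("A", "B", 0, 0, 0, 0, 1, 2, 3, 4))


class TestResourceLoad:
    @pytest.mark.parametrize("name,expected", [
        (APCS, 11), (CNP, 11), (KCS, 11), (MODIFIED_APCS, 11), (EIGHT_POINT, 9),
    ])
    def test_published_nns_points(self, name, expected):
        assert resource_load(STUDY_TWO_BY_TWO[name]).point == expected

    def test_no_score_baseline(self):
        assert nns_without_score(STUDY_N, STUDY_CAN).point == 16

    def test_every_high_subject_can(self):
        assert resource_load(TwoByTwo(10, 0, 1, 9)).point == 1

    def test_no_detection_raises(self):
        with pytest.raises(StatsError):
            resource_load(TwoByTwo(0, 10, 1, 9))

    def test_rounding_half_up(self):
        assert round_half_up(10.5) == 11 and round_half_up(10.49) == 10
        assert round_half_up(16.11) == 16


class TestStratifiedDetection:
    def test_uniform_outcome_cells_equal_overall(self):
        records = tuple(
            make_subject(subject_id=f"{sex}{age}", sex=sex, age=age,
                         outcome="CAN" if age % 2 else "negative")
            for sex in ("male", "female") for age in range(50, 75)
        )
        from crcscreen.cohort import Cohort
        cohort = Cohort(records=records)
        df = stratified_detection(cohort)
        # direct group-by oracle
        for _, row in df.iterrows():
            lo, hi = map(int, row["band"].split("-"))
            members = [r for r in records if r.sex == row["sex"] and lo <= r.age <= hi]
            k = sum(r.outcome == "CAN" for r in members)
            assert row["n"] == len(members) and row["n_can"] == k
            assert row["rate_pct"] == pytest.approx(100 * k / len(members))

    def test_empty_cell_flagged(self):
        from crcscreen.cohort import Cohort
        cohort = Cohort(records=(make_subject(sex="male", age=52),))
        df = stratified_detection(cohort)
        assert not df[(df.sex == "female")]["defined"].any()
        assert math.isnan(df[df.sex == "female"].iloc[0]["rate_pct"])

    def test_bands_must_partition(self):
        from crcscreen.cohort import Cohort
        cohort = Cohort(records=(make_subject(),))
        with pytest.raises(ValueError):
            stratified_detection(cohort, bands=((50, 60), (62, 74)))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    a=st.integers(1, 200), b=st.integers(1, 200),
    c=st.integers(1, 200), d=st.integers(1, 200),
)
def test_ci_invariants_on_random_tables(a, b, c, d):
    """All proportion CIs contain the point and stay in [0, 100]%."""
    t = TwoByTwo(a, b, c, d)
    ests = list(diagnostic_metrics(t).values())
    ests.append(high_risk_rate(t))
    ests.extend(detection_rates(t).values())
    for est in ests:
        assert 0.0 <= est.lo <= est.point <= est.hi <= 100.0
    rr_fwd, rr_rev = relative_risk(t), relative_risk(t.swapped())
    assert rr_rev.point == pytest.approx(1 / rr_fwd.point)
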