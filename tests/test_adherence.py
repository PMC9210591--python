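"""Unit and property tests for PDC scoring, index fills, and flags."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import adherits
from adherits.adherence import covered_days, max_uncovered_run
from adherits.errors import CohortInvariantError, ValidationError

from conftest import grid_coverage, intervals_to_grid, make_fills, make_patient


class TestClassCoverage:
    def test_overlapping_fills_push_forward(self):
        # 30-day fill at day 0 plus early refill at day 20: supply stacks to day 60
        intervals = adherits.class_coverage([(0, 30), (20, 30)], 0, 365)
        assert intervals == [(0, 60)]
        assert covered_days(intervals) == 60

    def test_single_year_fill(self):
        assert adherits.class_coverage([(0, 365)], 0, 365) == [(0, 365)]

    def test_gap_between_fills(self):
        intervals = adherits.class_coverage([(0, 10), (40, 10)], 0, 365)
        assert intervals == [(0, 10), (40, 50)]
        assert covered_days(intervals) == 20
        assert max_uncovered_run(intervals, 0, 365) == 365 - 50

    def test_same_day_fills_merge_to_one(self):
        # two fills on one day behave exactly like one fill of summed supply
        merged = adherits.class_coverage([(5, 30), (5, 60)], 0, 365)
        single = adherits.class_coverage([(5, 90)], 0, 365)
        assert merged == single == [(5, 95)]

    def test_empty_fill_list(self):
        assert adherits.class_coverage([], 0, 365) == []

    def test_window_truncation(self):
        assert adherits.class_coverage([(350, 90)], 0, 365) == [(350, 365)]

    def test_invalid_window(self):
        with pytest.raises(ValidationError):
            adherits.class_coverage([(0, 30)], 10, 10)

    fills_strategy = st.lists(
        st.tuples(st.integers(0, 200), st.integers(1, 120)), min_size=0, max_size=8)

    @given(fills=fills_strategy, window=st.tuples(st.integers(0, 50), st.integers(60, 250)))
    def test_matches_day_grid_oracle(self, fills, window):
        """Interval-based coverage equals the day-by-day supply-bank oracle."""
        ws, we = window
        intervals = adherits.class_coverage(fills, ws, we)
        assert np.array_equal(intervals_to_grid(intervals, ws, we),
                              grid_coverage(fills, ws, we))

    @given(fills=fills_strategy.filter(lambda f: len(f) > 0),
           idx=st.integers(0, 7), extra=st.integers(1, 60))
    def test_monotone_in_supply_and_fills(self, fills, idx, extra):
        """Increasing a fill's supply or adding a fill never reduces coverage."""
        base = covered_days(adherits.class_coverage(fills, 0, 365))
        idx = idx % len(fills)
        bigger = list(fills)
        bigger[idx] = (bigger[idx][0], bigger[idx][1] + extra)
        assert covered_days(adherits.class_coverage(bigger, 0, 365)) >= base
        added = list(fills) + [(100, extra)]
        assert covered_days(adherits.class_coverage(added, 0, 365)) >= base

    @given(fills=fills_strategy)
    def test_coverage_bounded_by_supply_and_window(self, fills):
        W = 365
        total = covered_days(adherits.class_coverage(fills, 0, W))
        supply_in_window = sum(s for d, s in fills if d < W)
        assert total <= min(W, supply_in_window) if fills else total == 0


class TestIndexFill:
    def test_fill_after_window_excludes(self):
        patient = make_patient(discharge_day=100)
        fills = make_fills([("P1", "statin", 108, 30)])  # day 8 post-discharge
        assert adherits.find_index_fill(patient, fills) is None

    def test_two_classes_same_day(self):
        patient = make_patient()
        fills = make_fills([("P1", "statin", 3, 30), ("P1", "beta_blocker", 3, 30)])
        index = adherits.find_index_fill(patient, fills)
        assert index.index_day == 3
        assert index.classes == ("beta_blocker", "statin")

    def test_later_class_not_in_index_set(self):
        # statin day 2, beta blocker day 5: only the statin defines the class set
        patient = make_patient()
        fills = make_fills([("P1", "statin", 2, 30), ("P1", "beta_blocker", 5, 30)])
        index = adherits.find_index_fill(patient, fills)
        assert index.index_day == 2
        assert index.classes == ("statin",)
        result = adherits.compute_pdc(patient, index, fills)
        assert set(result.pdc) == {"statin"}  # day-5 class contributes nothing

    def test_boundary_day_seven_included(self):
        patient = make_patient()
        fills = make_fills([("P1", "statin", 7, 30)])
        assert adherits.find_index_fill(patient, fills).index_day == 7

    def test_pre_discharge_fill_ignored(self):
        patient = make_patient(discharge_day=50)
        fills = make_fills([("P1", "statin", 45, 90), ("P1", "statin", 52, 30)])
        index = adherits.find_index_fill(patient, fills)
        assert index.index_day == 2
        assert index.supplies == {"statin": 30}


class TestComputePdc:
    def test_full_year_coverage(self):
        patient = make_patient()
        fills = make_fills([("P1", "statin", 0, 365)])
        index = adherits.find_index_fill(patient, fills)
        result = adherits.compute_pdc(patient, index, fills)
        assert result.pdc["statin"] == 1.0
        assert result.adherent and result.class_persistent["statin"]

    def test_death_censoring_at_threshold(self):
        # covered 80 of the 100 days before death: PDC exactly 0.80 -> adherent
        patient = make_patient(death_day=100)
        fills = make_fills([("P1", "statin", 0, 80)])
        index = adherits.find_index_fill(patient, fills)
        result = adherits.compute_pdc(patient, index, fills)
        assert result.window_days == 100
        assert result.pdc["statin"] == pytest.approx(0.80)
        assert result.adherent  # threshold is inclusive

    def test_average_across_classes(self):
        patient = make_patient()
        fills = make_fills([("P1", "statin", 0, 365), ("P1", "beta_blocker", 0, 90),
                            ("P1", "beta_blocker", 90, 92)])
        index = adherits.find_index_fill(patient, fills)
        result = adherits.compute_pdc(patient, index, fills)
        assert result.pdc["statin"] == 1.0
        assert result.pdc["beta_blocker"] == pytest.approx(182 / 365)
        assert result.average_pdc == pytest.approx((1.0 + 182 / 365) / 2)
        assert not result.adherent
        assert result.class_adherent["statin"] and not result.class_adherent["beta_blocker"]

    def test_gap_breaks_persistence(self):
        patient = make_patient()
        fills = make_fills([("P1", "statin", 0, 10), ("P1", "statin", 40, 10)])
        index = adherits.find_index_fill(patient, fills)
        result = adherits.compute_pdc(patient, index, fills)
        assert result.pdc["statin"] == pytest.approx(20 / 365)
        assert not result.class_persistent["statin"]

    def test_exact_30_day_gap_non_persistent(self):
        # gap of exactly 30 days mid-window; trailing gap removed by final fill
        patient = make_patient()
        fills = make_fills([("P1", "statin", 0, 30), ("P1", "statin", 60, 305)])
        index = adherits.find_index_fill(patient, fills)
        result = adherits.compute_pdc(patient, index, fills)
        assert not result.class_persistent["statin"]

    def test_29_day_gap_persistent(self):
        patient = make_patient()
        fills = make_fills([("P1", "statin", 0, 30), ("P1", "statin", 59, 306)])
        index = adherits.find_index_fill(patient, fills)
        result = adherits.compute_pdc(patient, index, fills)
        assert result.class_persistent["statin"]

    def test_trailing_gap_counts_against_persistence(self):
        patient = make_patient()
        fills = make_fills([("P1", "statin", 0, 330)])  # 35 uncovered trailing days
        index = adherits.find_index_fill(patient, fills)
        result = adherits.compute_pdc(patient, index, fills)
        assert result.pdc["statin"] == pytest.approx(330 / 365)
        assert not result.class_persistent["statin"]

    def test_death_on_discharge_rejected(self):
        patient = make_patient(death_day=0)
        fills = make_fills([("P1", "statin", 0, 30)])
        index = adherits.IndexFill("P1", 0, {"statin": 30})
        with pytest.raises(CohortInvariantError):
            adherits.compute_pdc(patient, index, fills)

    def test_adherent_iff_average_pdc_at_threshold(self):
        """adherent flag is exactly (average PDC >= 0.80) across random cohorts."""
        rng = np.random.default_rng(7)
        patient = make_patient()
        for _ in range(50):
            n_fills = rng.integers(1, 8)
            fills = make_fills([("P1", "statin", int(rng.integers(0, 8)) if i == 0
                                 else int(rng.integers(8, 360)), int(rng.integers(1, 120)))
                                for i in range(n_fills)])
            index = adherits.find_index_fill(patient, fills)
            result = adherits.compute_pdc(patient, index, fills)
            assert result.adherent == (result.average_pdc >= 0.80)
            assert 0 <= result.average_pdc <= 1


class TestProlongedFlags:
    def test_mixed_durations(self):
        index = adherits.IndexFill("P1", 0, {"statin": 90, "beta_blocker": 30})
        per_class, avg = adherits.prolonged_flags(index)
        assert per_class == {"statin": True, "beta_blocker": False}
        assert avg is False  # average 60 < 90

    def test_threshold_inclusive(self):
        index = adherits.IndexFill("P1", 0, {"statin": 90})
        per_class, avg = adherits.prolonged_flags(index)
        assert per_class["statin"] and avg

    def test_average_recomputed(self):
        supplies = {"statin": 100, "beta_blocker": 100, "secondary_antiplatelet": 80}
        index = adherits.IndexFill("P1", 0, supplies)
        per_class, avg = adherits.prolonged_flags(index)
        assert per_class == {"statin": True, "beta_blocker": True,
                             "secondary_antiplatelet": False}
        assert avg == (sum(supplies.values()) / 3 >= 90)
        assert avg is True


class TestScoreCohort:
    def test_all_index_day_zero_no_exclusions(self):
        patients = pd.DataFrame([make_patient(f"P{i}") for i in range(5)])
        fills = make_fills([(f"P{i}", "statin", 0, 90) for i in range(5)])
        results, exclusions, n_orphans = adherits.score_cohort(patients, fills)
        assert len(results) == 5 and len(exclusions) == 0 and n_orphans == 0

    def test_no_fills_excluded_with_reason(self):
        patients = pd.DataFrame([make_patient("P1"), make_patient("P2")])
        fills = make_fills([("P1", "statin", 0, 90)])
        results, exclusions, _ = adherits.score_cohort(patients, fills)
        assert list(exclusions["patient_id"]) == ["P2"]
        assert list(exclusions["reason"]) == ["no index fill"]

    def test_orphan_dispensations_counted(self):
        patients = pd.DataFrame([make_patient("P1")])
        fills = make_fills([("P1", "statin", 0, 90), ("GHOST", "statin", 0, 30)])
        _, _, n_orphans = adherits.score_cohort(patients, fills)
        assert n_orphans == 1

    def test_exclusions_match_generator_truth(self, small_cohort, small_scored):
        """Exclusion count equals the generator's count of patients built
        without a fill inside the index window."""
        _, _, truth = small_cohort
        _, exclusions, _ = small_scored
        assert len(exclusions) == truth.n_no_index_fill

    def test_negative_supply_rejected(self):
        patients = pd.DataFrame([make_patient("P1")])
        fills = make_fills([("P1", "statin", 0, -5)])
        with pytest.raises(ValidationError):
            adherits.score_cohort(patients, fills)
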