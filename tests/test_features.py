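"""Daily mobility features: staying time, entropy, transitions, occupancy, KDE."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mobisias.features import (
    FEATURE_NAMES,
    N_FEATURES,
    daily_vector,
    location_entropy,
    staying_time,
    transition_count,
    transition_counts,
    visit_density,
    visit_occupancy,
)

from helpers import make_day


class TestStayingTime:
    def test_full_home_evening(self):
        day = make_day([("Home", 16, 24)], observed=(0, 24))
        frac, minutes = staying_time(day, "Home", "evening")
        assert frac == pytest.approx(1.0)
        assert minutes == pytest.approx(480.0)

    def test_absent_class_is_zero(self):
        day = make_day([("Home", 0, 24)])
        frac, minutes = staying_time(day, "Leisure", "evening")
        assert frac == 0.0 and minutes == 0.0

    def test_half_half_evening(self):
        day = make_day([("Home", 16, 20), ("Education", 20, 24)], observed=(0, 24))
        assert staying_time(day, "Home", "evening")[0] == pytest.approx(0.5)
        assert staying_time(day, "Education", "evening")[0] == pytest.approx(0.5)

    def test_removed_time_excluded_from_denominator(self):
        day = make_day([("Home", 16, 20)], removed=[(20, 24)], observed=(0, 24))
        frac, minutes = staying_time(day, "Home", "evening")
        assert frac == pytest.approx(1.0)
        assert minutes == pytest.approx(240.0)

    def test_fully_removed_epoch_flagged_missing(self):
        day = make_day([("Home", 0, 16)], removed=[(16, 24)], observed=(0, 24))
        frac, _ = staying_time(day, "Home", "evening")
        assert math.isnan(frac)

    def test_epoch_minutes_sum_to_daily(self):
        day = make_day(
            [("Home", 0, 9.5), ("Transition", 9.5, 10), ("Education", 10, 15.25),
             ("Leisure", 15.25, 21), ("Home", 21, 24)],
            observed=(0, 24),
        )
        for cls in ("Home", "Education", "Leisure", "Transition"):
            daily = staying_time(day, cls, "daily")[1]
            parts = sum(staying_time(day, cls, e)[1] for e in ("morning", "evening", "night"))
            assert parts == pytest.approx(daily, abs=1 / 60)


class TestEntropy:
    def test_single_class_zero(self):
        day = make_day([("Home", 0, 24)])
        assert location_entropy(day.intervals) == 0.0

    def test_two_equal_classes_ln2(self):
        day = make_day([("Home", 0, 12), ("Education", 12, 24)])
        assert location_entropy(day.intervals) == pytest.approx(math.log(2), abs=1e-12)

    def test_known_composition(self):
        # p = (0.7, 0.2, 0.1): direct evaluation of -sum p ln p = 0.80182
        day = make_day([("Home", 0, 7), ("Education", 7, 9), ("Food", 9, 10)])
        expected = -(0.7 * math.log(0.7) + 0.2 * math.log(0.2) + 0.1 * math.log(0.1))
        assert location_entropy(day.intervals) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.80182, abs=1e-5)

    def test_transition_time_excluded(self):
        day = make_day([("Home", 0, 12), ("Transition", 12, 24)])
        assert location_entropy(day.intervals) == 0.0

    def test_no_labeled_time_missing(self):
        day = make_day([("Transition", 0, 24)])
        assert math.isnan(location_entropy(day.intervals))

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0.05, 10.0), min_size=1, max_size=9))
    def test_bounded_by_ln_n(self, weights):
        classes = ["Home", "OtherHouses", "Education", "Leisure", "Food",
                   "Supermarket", "Religious", "Service", "OutOfTown"]
        total = sum(weights)
        spec, pos = [], 0.0
        for c, w in zip(classes, weights):
            spec.append((c, pos, pos + 24 * w / total))
            pos += 24 * w / total
        h = location_entropy(make_day(spec).intervals)
        assert -1e-9 <= h <= math.log(len(weights)) + 1e-9


class TestTransitions:
    def test_unidirectional(self):
        day = make_day(
            [("Home", 0, 9), ("Transition", 9, 9.5), ("Education", 9.5, 17)],
            places={0: "h1", 2: "e1"},
        )
        assert transition_count(day, "Home", "Education") == 1
        assert transition_count(day, "Education", "Home") == 0

    def test_single_interval_no_transitions(self):
        day = make_day([("Home", 0, 24)])
        assert transition_counts(day) == {}

    def test_same_class_distinct_places_counted(self):
        day = make_day(
            [("Leisure", 18, 19), ("Leisure", 19, 20)], places={0: "l1", 1: "l2"}
        )
        assert transition_count(day, "Leisure", "Leisure") == 1

    def test_same_place_continuation_not_counted(self):
        day = make_day([("Home", 0, 12), ("Home", 12, 24)], places={0: "h1", 1: "h1"})
        assert transition_counts(day) == {}

    def test_removed_span_breaks_adjacency(self):
        day = make_day(
            [("Home", 0, 9), ("Education", 10, 17)],
            removed=[(9, 10)],
            places={0: "h1", 1: "e1"},
        )
        assert transition_counts(day) == {}

    def test_total_count_identity(self):
        day = make_day(
            [("Home", 0, 8), ("Transition", 8, 8.5), ("Education", 8.5, 12),
             ("Food", 12, 13), ("Education", 13, 16), ("Home", 16, 24)],
            places={0: "h1", 2: "e1", 3: "f1", 4: "e1", 5: "h1"},
        )
        non_transition = 5
        assert sum(transition_counts(day).values()) == non_transition - 1


class TestOccupancy:
    def test_home_all_day(self):
        day = make_day([("Home", 0, 24)])
        assert np.allclose(visit_occupancy(day, "Home"), 1.0)
        assert np.allclose(visit_occupancy(day, "Food"), 0.0)

    def test_single_evening_bin(self):
        day = make_day([("Leisure", 18, 21)])
        occ = visit_occupancy(day, "Leisure")
        expected = np.zeros(8)
        expected[6] = 1.0  # [18, 21)
        assert np.allclose(occ, expected)

    def test_bins_sum_at_most_one_across_classes(self):
        day = make_day(
            [("Home", 0, 10), ("Education", 10.5, 16), ("Leisure", 16, 19),
             ("Home", 20, 24)]
        )
        total = sum(
            visit_occupancy(day, c) for c in ("Home", "Education", "Leisure")
        )
        assert (total <= 1.0 + 1e-9).all()


class TestVisitDensity:
    def test_requires_two_points(self):
        with pytest.raises(ValueError):
            visit_density(np.array([12.0]))

    def test_peak_at_noon(self):
        grid, dens = visit_density(np.full(50, 12.0) + np.linspace(-0.2, 0.2, 50))
        assert abs(grid[np.argmax(dens)] - 12.0) < 0.5

    def test_integrates_to_one(self):
        rng = np.random.default_rng(3)
        grid, dens = visit_density(rng.uniform(0, 24, 200), np.linspace(0, 24, 24001))
        area = np.trapezoid(dens, grid)
        assert area == pytest.approx(1.0, abs=1e-6)

    def test_uniform_sample_is_flat(self):
        x = (np.arange(4000) * 24.0 / 4000) % 24
        _, dens = visit_density(x)
        assert dens.max() / dens.min() == pytest.approx(1.0, abs=0.05)


class TestDailyVector:
    def test_length_and_names(self):
        assert N_FEATURES == len(FEATURE_NAMES) == 204
        day = make_day([("Home", 0, 24)], observed=(0, 24))
        vec, mask = daily_vector(day)
        assert vec.shape == (204,) and mask.shape == (204,)

    def test_all_home_day(self):
        day = make_day([("Home", 0, 24)], observed=(0, 24))
        vec, _ = daily_vector(day)
        f = dict(zip(FEATURE_NAMES, vec))
        assert f["stay_frac_Home_daily"] == pytest.approx(1.0)
        assert f["entropy"] == 0.0
        assert all(v == 0 for k, v in f.items() if k.startswith("trans_"))

    def test_saturday_calendar_features(self):
        from datetime import date

        day = make_day([("Home", 0, 24)], date=date(2018, 3, 10))
        vec, _ = daily_vector(day)
        f = dict(zip(FEATURE_NAMES, vec))
        assert f["is_weekend"] == 1.0 and f["day_of_week"] == 5.0

    def test_invariant_to_same_class_resplit(self):
        a = make_day([("Home", 0, 10), ("Education", 10, 24)],
                     places={0: "h1", 1: "e1"}, observed=(0, 24))
        b = make_day([("Home", 0, 4), ("Home", 4, 10), ("Education", 10, 24)],
                     places={0: "h1", 1: "h1", 2: "e1"}, observed=(0, 24))
        va, _ = daily_vector(a)
        vb, _ = daily_vector(b)
        assert np.allclose(va, vb)


def test_feature_table_shape(tiny_cohort):
    tab = tiny_cohort.table
    assert list(tab.features.columns) == FEATURE_NAMES
    assert tab.features.shape == tab.mask.shape
    assert ((tab.features[[c for c in FEATURE_NAMES if c.startswith("stay_frac")]] >= 0).all().all())
    assert (tab.features["entropy"] >= 0).all()
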