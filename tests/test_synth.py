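"""Synthetic cohort generator: maps, SIAS sampling, profiles, simulation, gaps."""

from datetime import date

import numpy as np
import pytest

from mobisias.clustering import extract_stays
from mobisias.geo import haversine_m
from mobisias.io import ParticipantTrace
from mobisias.synth import (
    CohortConfig,
    EffectConfig,
    GapConfig,
    MapConfig,
    NoiseConfig,
    build_profile,
    generate_cohort,
    generate_map,
    inject_gaps,
    sample_sias,
    simulate_day,
)


class TestGenerateMap:
    def test_counts_and_determinism(self):
        cfg = MapConfig(n_houses=4, n_education=1, n_leisure=1, n_food=1,
                        n_supermarket=1, n_religious=1, n_service=1, n_out_of_town=2)
        m1 = generate_map(cfg, 7)
        m2 = generate_map(cfg, 7)
        assert len(m1) == 4 + 6 + 2
        assert [(p.place_id, p.lat, p.lon) for p in m1.places] == [
            (p.place_id, p.lat, p.lon) for p in m2.places
        ]

    def test_out_of_town_places_beyond_radius(self):
        m = generate_map(MapConfig(n_houses=3), 1)
        oot = [p for p in m.places if p.place_id.startswith("oot")]
        assert oot
        for p in oot:
            assert haversine_m((p.lat, p.lon), m.town_center) > m.town_radius_m

    def test_minimum_separation(self):
        cfg = MapConfig(n_houses=20)
        m = generate_map(cfg, 2)
        core = [p for p in m.places if not m.is_out_of_town(p.lat, p.lon)]
        for i, a in enumerate(core):
            for b in core[i + 1 :]:
                assert haversine_m((a.lat, a.lon), (b.lat, b.lon)) >= cfg.min_separation_m * 0.99

    def test_zero_category_rejected(self):
        with pytest.raises(ValueError):
            generate_map(MapConfig(n_houses=0), 1)


class TestSampleSias:
    def test_empty(self):
        assert sample_sias(0, 1).size == 0

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError):
            sample_sias(-1, 1)

    def test_range_and_mean(self):
        draws = sample_sias(10000, 42)
        assert draws.min() >= 11 and draws.max() <= 54
        assert abs(draws.mean() - 29.91) < 0.5


@pytest.fixture(scope="module")
def shared_map():
    return generate_map(MapConfig(n_houses=8), 3)


class TestBuildProfile:
    def test_zero_effects_identical_expectations(self, shared_map):
        zero = EffectConfig.zero()
        p1 = build_profile(11, shared_map, zero, seed=5, intercept_scale=0.0)
        p2 = build_profile(54, shared_map, zero, seed=5, intercept_scale=0.0)
        assert p1.expected == p2.expected
        assert p1.day_sigma == p2.day_sigma

    def test_evening_home_increases_with_sias(self, shared_map):
        eff = EffectConfig()
        lo = build_profile(11, shared_map, eff, seed=5, intercept_scale=0.0)
        hi = build_profile(54, shared_map, eff, seed=5, intercept_scale=0.0)
        for dt in ("wd", "we"):
            assert hi.expected_evening_home_minutes(dt) > lo.expected_evening_home_minutes(dt)

    def test_leisure_decreases_with_sias(self, shared_map):
        eff = EffectConfig()
        lo = build_profile(11, shared_map, eff, seed=5, intercept_scale=0.0)
        hi = build_profile(54, shared_map, eff, seed=5, intercept_scale=0.0)
        assert hi.expected[("leisure", "we")] < lo.expected[("leisure", "we")]
        assert hi.expected[("leisure", "wd")] < lo.expected[("leisure", "wd")]

    def test_supermarket_increases_with_sias(self, shared_map):
        eff = EffectConfig()
        lo = build_profile(11, shared_map, eff, seed=5, intercept_scale=0.0)
        hi = build_profile(54, shared_map, eff, seed=5, intercept_scale=0.0)
        assert hi.expected[("supermarket", "we")] >= lo.expected[("supermarket", "we")]

    def test_routine_diversity_non_increasing(self, shared_map):
        eff = EffectConfig()
        sizes = []
        for total in (11, 30, 54):
            p = build_profile(total, shared_map, eff, seed=5, intercept_scale=0.0)
            sizes.append(len(p.routine["leisure"]) + len(p.routine["food"]))
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_negative_dwell_clamped_to_zero(self, shared_map):
        eff = EffectConfig(leisure_we=-500.0)
        p = build_profile(54, shared_map, eff, seed=5, intercept_scale=0.0)
        assert p.expected[("leisure", "we")] == 0.0


def _all_home_profile(shared_map, seed=5):
    """A profile whose weekly template is empty: home around the clock."""
    p = build_profile(30, shared_map, EffectConfig.zero(), seed=seed,
                      intercept_scale=0.0)
    p.expected = {k: 0.0 for k in p.expected}
    p.template = {}
    p.lunch_dows = frozenset()
    return p


class TestSimulateDay:
    def test_all_home_day_zero_jitter(self, shared_map):
        p = _all_home_profile(shared_map)
        times, lats, lons, gt_stays, gt_trans = simulate_day(
            p, shared_map, date(2018, 3, 5), seed=1, jitter_sigma_m=0.0
        )
        assert len(times) == 576
        home = shared_map[p.home_place_id]
        assert np.allclose(lats, home.lat) and np.allclose(lons, home.lon)
        assert len(gt_stays) == 1 and gt_trans == []
        assert gt_stays[0].cls == "Home"

    def test_ground_truth_matches_schedule(self, shared_map):
        eff = EffectConfig()
        p = build_profile(30, shared_map, eff, seed=9)
        times, lats, lons, gt_stays, gt_trans = simulate_day(
            p, shared_map, date(2018, 3, 5), seed=2, jitter_sigma_m=0.0
        )
        # weekday: home, school... stays ordered, non-overlapping, in-day
        assert all(a.end <= b.start for a, b in zip(gt_stays, gt_stays[1:]))
        assert len(gt_trans) == len(gt_stays) - 1 - sum(
            1 for a, b in zip(gt_stays, gt_stays[1:]) if a.end == b.start
        )
        assert times.min() >= gt_stays[0].start

    def test_jitter_tail_bound(self, shared_map):
        # sigma = 10 m: >= 99% of stay points within 40 m of the centroid
        p = _all_home_profile(shared_map)
        times, lats, lons, _, _ = simulate_day(
            p, shared_map, date(2018, 3, 5), seed=3, jitter_sigma_m=10.0
        )
        home = shared_map[p.home_place_id]
        d = np.array([haversine_m((la, lo), (home.lat, home.lon))
                      for la, lo in zip(lats, lons)])
        assert (d <= 40.0).mean() >= 0.99


class TestInjectGaps:
    def _trace(self):
        t0 = 1_520_208_000
        times = t0 + np.arange(576) * 150
        return ParticipantTrace("p", times, np.full(576, 38.0), np.full(576, -78.5))

    def test_empty_config_is_noop(self):
        tr = self._trace()
        out, gaps = inject_gaps(tr, GapConfig.none(), 1)
        assert gaps == [] and len(out) == len(tr)

    def test_forced_gap_removes_only_window(self):
        tr = self._trace()
        s = int(tr.times[0]) + 7200
        out, gaps = inject_gaps(tr, GapConfig(rate_per_day=0, patchy_day_prob=0,
                                              forced=((s, s + 1200),)), 1)
        assert gaps == [(s, s + 1200)]
        assert not ((out.times >= s) & (out.times < s + 1200)).any()
        assert len(tr) - len(out) == 8

    def test_forced_long_gap_is_removable_regime(self):
        from mobisias.clustering import gap_regime

        tr = self._trace()
        s = int(tr.times[0]) + 7200
        out, gaps = inject_gaps(tr, GapConfig(rate_per_day=0, patchy_day_prob=0,
                                              forced=((s, s + 2700),)), 1)
        (lo, hi), = gaps
        assert gap_regime(hi - lo) == "removable"


class TestGenerateCohort:
    def test_point_budget(self):
        cfg = CohortConfig(n_participants=2, n_days=1, map=MapConfig(n_houses=6))
        b = generate_cohort(cfg, 1)
        assert len(b.traces) == 2
        for tr in b.traces.values():
            assert len(tr) <= 576  # 86400 / 150

    def test_both_groups_present(self):
        cfg = CohortConfig(n_participants=60, n_days=1, map=MapConfig(n_houses=70))
        b = generate_cohort(cfg, 4)
        highs = sum(1 for v in b.sias.values() if v >= 34)
        assert 0 < highs < 60

    def test_deterministic_digest(self):
        cfg = CohortConfig(n_participants=3, n_days=2, map=MapConfig(n_houses=6))
        assert generate_cohort(cfg, 9).digest() == generate_cohort(cfg, 9).digest()


class TestExactRecovery:
    def test_zero_noise_recovers_ground_truth(self):
        # no jitter, no gaps: every true stay of duration >= 2t is recovered
        # in order with the right place
        cfg = CohortConfig(
            n_participants=3, n_days=2, map=MapConfig(n_houses=6),
            noise=NoiseConfig(jitter_sigma_m=0.0, gaps=GapConfig.none()),
        )
        b = generate_cohort(cfg, 5)
        for pid, tr in b.traces.items():
            stays, _ = extract_stays(tr)
            gt = [s for s in b.ground_truth[pid].stays if s.end - s.start >= 1200]
            matched = []
            for g in gt:
                hit = [
                    s for s in stays
                    if min(s.end, g.end) - max(s.start, g.start) > 0
                    and haversine_m((s.lat, s.lon),
                                    (b.place_map[g.place_id].lat,
                                     b.place_map[g.place_id].lon)) < 30.0
                ]
                assert hit, f"unrecovered stay {g}"
                matched.append(hit[0].start)
            assert matched == sorted(matched)


def test_generator_level_effect_directions():
    """SIAS vs ground-truth evening-home and entropy, without inference."""
    import math

    cfg = CohortConfig(n_participants=120, n_days=7, map=MapConfig(n_houses=130),
                       noise=NoiseConfig(jitter_sigma_m=0.0, gaps=GapConfig.none()))
    b = generate_cohort(cfg, 21)
    sias, home_ev, entropy = [], [], []
    for pid, gt in b.ground_truth.items():
        ev = 0.0
        shares: dict[str, float] = {}
        for s in gt.stays:
            day0 = (s.start // 86400) * 86400
            a, bb = day0 + 16 * 3600, day0 + 24 * 3600
            if s.cls == "Home":
                ev += max(0, min(s.end, bb) - max(s.start, a))
            shares[s.cls] = shares.get(s.cls, 0.0) + (s.end - s.start)
        tot = sum(shares.values())
        h = -sum(v / tot * math.log(v / tot) for v in shares.values() if v > 0)
        sias.append(b.sias[pid])
        home_ev.append(ev)
        entropy.append(h)
    r_home = np.corrcoef(sias, home_ev)[0, 1]
    r_ent = np.corrcoef(sias, entropy)[0, 1]
    assert r_home > 0
    assert r_ent < 0
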