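"""Trial segmentation, metrics, direction maps and template clustering."""

from __future__ import annotations

import numpy as np
import pytest

from forageseq import behavior as bh
from forageseq.core import BEHAVIOR_DT, BehaviorFrame, Condition, Event, SessionRecording
from forageseq.synthetic import SimConfig, simulate_behavior


def make_frame(x, y, direction=None, speed=None, t0=0.0):
    x = np.asarray(x, float)
    n = x.size
    t = t0 + np.arange(n) * BEHAVIOR_DT
    if direction is None:
        dx = np.diff(x, append=x[-1])
        dy = np.diff(np.asarray(y, float), append=y[-1])
        with np.errstate(invalid="ignore"):
            direction = np.degrees(np.arctan2(dy, dx)) % 360
    if speed is None:
        speed = np.full(n, 15.0)
    return BehaviorFrame(t, x, np.asarray(y, float), np.asarray(direction, float),
                         np.asarray(speed, float), np.ones(n, dtype=bool))


def session_with_events(events):
    t = np.arange(0, 60, 0.04)
    return SessionRecording(
        "s", Condition.LIGHT, t, np.zeros(t.size), np.zeros(t.size), {},
        np.zeros(61_000), events=events,
    )


class TestSegmentTrials:
    def test_counts_complete_trials(self):
        ev = [
            Event("goal_reward", 1.0, "goal"),
            Event("zone_entry", 2.0, "A1"),
            Event("foraging_reward", 3.0),
            Event("zone_entry", 4.0, "goal"),
            Event("goal_reward", 5.0, "goal"),
            Event("zone_entry", 6.0, "B1"),
            Event("foraging_reward", 7.0),
            Event("zone_entry", 8.0, "goal"),
            Event("goal_reward", 9.0, "goal"),
        ]
        trials = bh.segment_trials(session_with_events(ev))
        assert len(trials) == 2
        assert trials[0].span == (1.0, 5.0)
        assert trials[0].foraging_segment == (1.0, 2.0)
        assert trials[0].goal_segment == (3.0, 4.0)

    def test_partial_trailing_trial_dropped(self):
        ev = [
            Event("goal_reward", 1.0, "goal"),
            Event("zone_entry", 2.0, "A1"),
            Event("foraging_reward", 3.0),
            Event("zone_entry", 3.5, "B1"),  # mid-trial, never completed
        ]
        assert bh.segment_trials(session_with_events(ev)) == []

    def test_event_order_violation(self):
        ev = [
            Event("goal_reward", 1.0, "goal"),
            Event("foraging_reward", 2.0),
            Event("foraging_reward", 3.0),
            Event("goal_reward", 4.0, "goal"),
        ]
        with pytest.raises(bh.EventOrderError, match="event-order"):
            bh.segment_trials(session_with_events(ev))

    def test_matches_generator_ground_truth(self):
        cfg = SimConfig(seed=21, n_trials=10)
        beh, labels = simulate_behavior(cfg)
        sess = SessionRecording(
            "s", Condition.LIGHT, beh["t"][::4], beh["x"][::4], beh["y"][::4], {},
            np.zeros(int(beh["t"][-1] * 1000) + 1000), events=beh["events"],
            zones=cfg.zones,
        )
        trials = bh.segment_trials(sess)
        assert len(trials) == 10
        # each trial starts at the generator's recorded trial start (the
        # preceding goal reward) to within one frame
        np.testing.assert_allclose(
            [t.span[0] for t in trials], beh["trial_starts"], atol=2 * BEHAVIOR_DT
        )


class TestTrialMetrics:
    def test_straight_return_normalizes_to_one(self):
        x = np.linspace(0, 30, 301)
        frame = make_frame(x, np.zeros_like(x))
        tr = bh.TrialRecord(0, (0.0, 3.0), (0.0, 1.0), (0.0, 3.0), 0.0, 3.0)
        m = bh.trial_metrics([tr], frame)
        assert m["median_goal_distance_norm"] == pytest.approx(1.0, abs=1e-6)

    def test_semicircular_return_gives_pi_over_two(self):
        a = np.linspace(0, np.pi, 500)
        frame = make_frame(10 * np.cos(a), 10 * np.sin(a))
        t_end = frame.t[-1]
        tr = bh.TrialRecord(0, (0.0, t_end), (0.0, 0.1), (0.0, t_end), 0.0, t_end)
        m = bh.trial_metrics([tr], frame)
        assert m["median_goal_distance_norm"] == pytest.approx(np.pi / 2, rel=1e-3)

    def test_rewards_per_minute_arithmetic(self):
        # 3 complete trials (6 rewards) in a 12-min frame -> 0.5 rewards/min
        n = 12 * 60 * 100
        frame = make_frame(np.zeros(n), np.zeros(n))
        trials = [
            bh.TrialRecord(i, (10.0 * i, 10.0 * i + 5), (10.0 * i, 10.0 * i + 2),
                           (10.0 * i + 3, 10.0 * i + 4), 10.0 * i + 3, 10.0 * i + 4)
            for i in range(3)
        ]
        m = bh.trial_metrics(trials, frame)
        assert m["rewards_per_min"] == pytest.approx(6 / 12.0, rel=1e-3)


class TestDirectionVectorMap:
    def test_single_heading_gives_unit_vector(self):
        x = np.linspace(-20, 20, 300)
        frame = make_frame(x, np.zeros_like(x), direction=np.zeros(300))
        mp = bh.direction_vector_map(frame, (frame.t[0], frame.t[-1]))
        vis = mp.visited
        assert vis.any()
        np.testing.assert_allclose(np.abs(mp.m[vis]), 1.0, atol=1e-12)
        # 0 deg lies in the [0, 20) bin whose center is 10 deg
        np.testing.assert_allclose(np.degrees(np.angle(mp.m[vis])) % 360, 10.0)

    def test_opposite_passes_cancel(self):
        # fast crossings: one <200-ms dwell per bin per pass
        x = np.concatenate([np.linspace(-20, 20, 150), np.linspace(20, -20, 150)])
        d = np.concatenate([np.zeros(150), np.full(150, 180.0)])
        frame = make_frame(x, np.zeros_like(x), direction=d)
        mp = bh.direction_vector_map(frame, (frame.t[0], frame.t[-1]))
        assert np.all(np.abs(mp.m[mp.visited]) < 1e-12)

    def test_two_heading_passes_vector_average(self):
        # headings discretize to the 10- and 90-deg bin centers (80 deg
        # apart); the mean of the two unit vectors has length cos(40 deg)
        # at the bisector 50 deg
        x = np.concatenate([np.linspace(-20, 20, 150), np.linspace(-20, 20, 150)])
        d = np.concatenate([np.zeros(150), np.full(150, 80.0)])
        frame = make_frame(x, np.zeros_like(x), direction=d)
        mp = bh.direction_vector_map(frame, (frame.t[0], frame.t[-1]))
        vis = mp.visited
        np.testing.assert_allclose(np.abs(mp.m[vis]), np.cos(np.radians(40)), atol=1e-12)
        np.testing.assert_allclose(np.degrees(np.angle(mp.m[vis])) % 360, 50.0, atol=1e-9)

    def test_empty_segment_gives_empty_map(self):
        frame = make_frame(np.zeros(10), np.zeros(10), speed=np.zeros(10))
        frame.valid[:] = False
        mp = bh.direction_vector_map(frame, (frame.t[0], frame.t[-1]))
        assert not mp.visited.any()


def random_map(rng, n_visited=60):
    m = np.zeros((bh.N_SPATIAL_BINS, bh.N_SPATIAL_BINS), dtype=complex)
    vis = np.zeros_like(m, dtype=bool)
    idx = rng.choice(m.size, size=n_visited, replace=False)
    lengths = rng.uniform(0, 1, n_visited)
    angles = rng.uniform(0, 2 * np.pi, n_visited)
    m.flat[idx] = lengths * np.exp(1j * angles)
    vis.flat[idx] = True
    return bh.DirectionVectorMap(0, m, vis)


class TestTrialDistance:
    def test_identity_antiparallel_orthogonal(self):
        rng = np.random.default_rng(0)
        mp = random_map(rng)
        assert bh.trial_distance(mp, mp) == pytest.approx(0.0, abs=1e-12)
        anti = bh.DirectionVectorMap(1, -mp.m, mp.visited)
        assert bh.trial_distance(mp, anti) == pytest.approx(2.0, abs=1e-12)
        orth = bh.DirectionVectorMap(2, 1j * mp.m, mp.visited)
        assert bh.trial_distance(mp, orth) == pytest.approx(1.0, abs=1e-12)

    def test_metric_axioms_over_random_pairs(self):
        rng = np.random.default_rng(1)
        maps = [random_map(rng) for _ in range(40)]
        for _ in range(1000):
            i, j = rng.integers(0, len(maps), 2)
            d_ij = bh.trial_distance(maps[i], maps[j])
            d_ji = bh.trial_distance(maps[j], maps[i])
            assert d_ij == pytest.approx(d_ji, abs=1e-12)
            assert -1e-12 <= d_ij <= 2 + 1e-12

    def test_disjoint_coverage_is_nan(self):
        m1 = np.zeros((20, 20), complex)
        v1 = np.zeros((20, 20), bool)
        v1[0, 0] = True
        m1[0, 0] = 1
        m2 = np.zeros((20, 20), complex)
        v2 = np.zeros((20, 20), bool)
        v2[5, 5] = True
        m2[5, 5] = 1
        d = bh.trial_distance(
            bh.DirectionVectorMap(0, m1, v1), bh.DirectionVectorMap(1, m2, v2)
        )
        assert np.isnan(d)


@pytest.fixture(scope="module")
def cohort_060():
    cfg = SimConfig(seed=33, n_trials=120, sequence_fraction_true=0.6)
    beh, labels = simulate_behavior(cfg)
    sess = SessionRecording(
        "s", Condition.LIGHT, beh["t"][::4], beh["x"][::4], beh["y"][::4], {},
        np.zeros(10), events=beh["events"], zones=cfg.zones,
    )
    from forageseq.core import resample_behavior

    frame = resample_behavior(sess)
    trials = bh.segment_trials(sess)
    maps = [bh.direction_vector_map(frame, tr, i) for i, tr in enumerate(trials)]
    return labels, maps


class TestClusterTemplates:
    def test_single_template_cohort_recovers_one_template(self, cohort_060):
        labels, maps = cohort_060
        templates = bh.cluster_templates(maps)
        assert len(templates) == 1
        assert len(templates[0].member_trials) > 30

    def test_invariant_to_trial_order(self, cohort_060):
        _, maps = cohort_060
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(maps))
        t1 = bh.cluster_templates(maps)
        t2 = bh.cluster_templates([maps[i] for i in perm])
        assert len(t1) == len(t2)
        members2 = {frozenset(perm[t.member_trials]) for t in t2}
        assert {frozenset(t.member_trials) for t in t1} == members2

    def test_sequence_fraction_recovery(self, cohort_060):
        labels, maps = cohort_060
        templates = bh.cluster_templates(maps)
        flags, _, frac = bh.match_sequence_trials(maps, templates)
        true_frac = np.mean([l != "random" for l in labels])
        assert abs(frac - true_frac) < 0.1

    def test_member_trials_match_own_template(self, cohort_060):
        _, maps = cohort_060
        templates = bh.cluster_templates(maps)
        tpl = templates[0]
        rs = [
            bh.template_correlation(maps[i], tpl) for i in tpl.member_trials
        ]
        assert np.mean(np.asarray(rs) > 0.6) > 0.9

    def test_random_cohort_yields_no_templates(self):
        cfg = SimConfig(seed=40, n_trials=100, sequence_fraction_true=0.0)
        beh, _ = simulate_behavior(cfg)
        sess = SessionRecording(
            "s", Condition.LIGHT, beh["t"][::4], beh["x"][::4], beh["y"][::4], {},
            np.zeros(10), events=beh["events"], zones=cfg.zones,
        )
        from forageseq.core import resample_behavior

        frame = resample_behavior(sess)
        trials = bh.segment_trials(sess)
        maps = [bh.direction_vector_map(frame, tr, i) for i, tr in enumerate(trials)]
        assert bh.cluster_templates(maps) == []

    def test_no_templates_means_zero_fraction(self, cohort_060):
        _, maps = cohort_060
        flags, best, frac = bh.match_sequence_trials(maps, [])
        assert frac == 0.0
        assert not flags.any()
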