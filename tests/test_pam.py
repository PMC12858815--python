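"""Tests of wear-time rules, bouts, macro/micro parameters and entropy."""

import numpy as np
import pytest
from scipy.stats import norm

from mobgait import ImuRecording, PamConfig
from mobgait.pam import (
    BoutStride,
    WalkingBout,
    aggregate_macro,
    classify_wb,
    compute_macro_day,
    detect_nonwear,
    detect_walking_bouts,
    estimate_micro,
    information_entropy,
    probs_from_episodes,
    run_pam,
    select_valid_days,
    state_label,
    wear_seconds,
    N_STATES,
    STATE_LABELS,
)
from mobgait.pam.nonwear import WearInterval
from mobgait.synth import (
    ActivitySchedule,
    Episode,
    generate_week_recording,
    phenotype_presets,
    plan_day,
    render_day,
)

FS = 8.0  # coarse rate is enough for wear-time logic


def _render(episodes, fs=FS, seed=0):
    ph = phenotype_presets("PD")
    plan, truth = plan_day(ActivitySchedule(episodes), ph, np.random.default_rng(seed))
    left, right = render_day(plan, fs, seed)
    return left, right, truth


class TestNonwear:
    def test_active_signal_is_one_wear_interval(self):
        left, _, _ = _render([Episode("active", 0.0, 3600.0, intensity="medium")])
        intervals = detect_nonwear(left)
        assert len(intervals) == 1 and intervals[0].is_wear

    def test_long_still_block_flagged_exactly(self):
        eps = [
            Episode("active", 0.0, 3600.0, intensity="medium"),
            Episode("nonwear", 3600.0, 120 * 60.0),
            Episode("active", 3600.0 + 120 * 60.0, 3600.0, intensity="medium"),
        ]
        left, _, _ = _render(eps)
        nonwear = [iv for iv in detect_nonwear(left) if not iv.is_wear]
        assert len(nonwear) == 1
        assert nonwear[0].start == pytest.approx(3600.0, abs=2.0)
        assert nonwear[0].end == pytest.approx(3600.0 + 7200.0, abs=2.0)

    def test_short_still_block_not_flagged(self):
        eps = [
            Episode("active", 0.0, 3600.0, intensity="medium"),
            Episode("nonwear", 3600.0, 60 * 60.0),
            Episode("active", 7200.0, 3600.0, intensity="medium"),
        ]
        left, _, _ = _render(eps)
        assert all(iv.is_wear for iv in detect_nonwear(left))

    def test_partition_covers_recording(self):
        eps = [
            Episode("sedentary", 0.0, 1800.0),
            Episode("nonwear", 1800.0, 100 * 60.0),
            Episode("sedentary", 1800.0 + 6000.0, 1800.0),
        ]
        left, _, _ = _render(eps)
        intervals = detect_nonwear(left)
        total = sum(iv.duration for iv in intervals)
        assert total == pytest.approx(left.duration, abs=1e-9)
        for a, b in zip(intervals, intervals[1:]):
            assert b.start == pytest.approx(a.end, abs=1e-9)


class TestValidDays:
    def test_mixed_week(self):
        valid, included = select_valid_days([9, 9, 7, 10, 0, 8.5, 13])
        assert valid == [0, 1, 3, 5]
        assert included

    def test_two_days_excluded(self):
        valid, included = select_valid_days([9, 9])
        assert valid == [0, 1] and not included

    def test_boundaries_inclusive(self):
        valid, included = select_valid_days([8.0, 12.0, 8.0])
        assert valid == [0, 1, 2] and included


class TestBouts:
    def test_duration_classes(self):
        assert classify_wb(45.0) == "medium"
        assert classify_wb(30.0) == "short"
        assert classify_wb(60.0) == "medium"
        assert classify_wb(61.0) == "long"
        assert classify_wb(10.0) == "short"
        assert classify_wb(9.9) == "subthreshold"

    def test_scheduled_bouts_stratified(self):
        t0 = 0.0
        eps, cursor = [], t0
        for dur in (20.0, 45.0, 90.0):
            eps.append(Episode("sedentary", cursor, 60.0))
            cursor += 60.0
            eps.append(Episode("walking", cursor, dur, cadence=100.0))
            cursor += dur
        eps.append(Episode("sedentary", cursor, 60.0))
        left, right, truth = _render(eps, fs=25.6)
        wear = detect_nonwear(left)
        bouts = detect_walking_bouts(left, right, wear)
        assert [b.wb_class for b in bouts] == ["short", "medium", "long"]
        assert [b.wb_class for b in truth.bouts] == ["short", "medium", "long"]

    def test_brief_pause_merges_into_one_bout(self):
        eps = [
            Episode("sedentary", 0.0, 60.0),
            Episode("walking", 60.0, 15.0, cadence=100.0),
            Episode("sedentary", 75.0, 2.0),
            Episode("walking", 77.0, 15.0, cadence=100.0),
            Episode("sedentary", 92.0, 60.0),
        ]
        left, right, _ = _render(eps, fs=25.6)
        bouts = detect_walking_bouts(left, right, detect_nonwear(left))
        assert len(bouts) == 1

    def test_subthreshold_counts_steps_not_bouts(self):
        eps = [
            Episode("sedentary", 0.0, 60.0),
            Episode("walking", 60.0, 8.0, cadence=100.0),
            Episode("sedentary", 68.0, 60.0),
        ]
        left, right, _ = _render(eps, fs=25.6)
        bouts = detect_walking_bouts(left, right, detect_nonwear(left))
        assert len(bouts) == 1
        assert bouts[0].wb_class == "subthreshold"
        assert bouts[0].steps > 0


def _quiet_recording(duration, fs=FS):
    n = int(duration * fs)
    acc = np.tile([0.0, 0.0, 1.0], (n, 1))
    return ImuRecording(acc=acc, gyr=np.zeros((n, 3)), fs=fs)


def _bout_with_steps(start, end, step_times):
    strides = [
        BoutStride(foot="left" if i % 2 else "right", start=t - 1.0, end=t,
                   gait_velocity=1.0, stride_length=1.2)
        for i, t in enumerate(step_times)
    ]
    return WalkingBout(start=start, end=end, wb_class=classify_wb(end - start),
                       strides=strides)


class TestMacro:
    def test_sedentary_day(self):
        rec = _quiet_recording(600.0)
        wear = [WearInterval(0.0, 600.0, True)]
        macro = compute_macro_day([], wear, rec, rec)
        assert macro.step_count == 0
        assert macro.mvpa_minutes == 0
        assert macro.active_sedentary_ratio == 0.0

    def test_mvpa_minutes_from_cadence(self):
        # three walking minutes at 95 / 95 / 85 steps -> 2 MVPA minutes
        rec = _quiet_recording(300.0)
        wear = [WearInterval(0.0, 300.0, True)]
        times = np.concatenate([
            np.linspace(0.1, 59.9, 95),
            np.linspace(60.1, 119.9, 95),
            np.linspace(120.1, 179.9, 85),
        ])
        bout = _bout_with_steps(0.0, 180.0, times)
        macro = compute_macro_day([bout], wear, rec, rec)
        assert macro.mvpa_minutes == 2
        assert macro.step_count == 275
        assert macro.active_minutes == 3
        assert macro.sedentary_minutes == 2

    def test_aggregate_median_and_max(self):
        from mobgait.pam.macro import DailyMacro
        days = [
            DailyMacro(i, 9.0, 10, 3, c, 90.0, 5000, 60, 400, 0.15, 20)
            for i, c in enumerate([5, 7, 9])
        ]
        agg = aggregate_macro(days)
        assert agg["wb_long"] == 7.0
        assert agg["max_long_wb_per_day"] == 9.0
        days = [DailyMacro(i, 9.0, 10, 3, c, 90.0, 5000, 60, 400, 0.15, 20)
                for i, c in enumerate([3, 4, 4, 10])]
        agg = aggregate_macro(days)
        assert agg["wb_long"] == 4.0
        assert agg["max_long_wb_per_day"] == 10.0

    def test_identical_days_median_equals_max(self):
        from mobgait.pam.macro import DailyMacro
        days = [DailyMacro(i, 9.0, 10, 3, 6, 90.0, 5000, 60, 400, 0.15, 20)
                for i in range(3)]
        agg = aggregate_macro(days)
        assert agg["wb_long"] == agg["max_long_wb_per_day"] == 6.0


class TestMicro:
    def test_degenerate_distribution(self):
        est = estimate_micro([1.0] * 200)
        assert est.mode == 1.0 and est.p95 == 1.0 and est.available

    def test_minimum_bout_rule(self):
        assert not estimate_micro(list(range(9))).available
        assert estimate_micro(list(range(10))).available

    def test_normal_mode_and_p95(self):
        rng = np.random.default_rng(12)
        x = rng.normal(1.0, 0.1, 500)
        est = estimate_micro(x)
        assert est.mode == pytest.approx(1.0, abs=0.05)
        # closed-form Normal quantile: 1 + 0.1 * z_0.95 = 1.1645
        assert est.p95 == pytest.approx(1.0 + 0.1 * norm.ppf(0.95), abs=0.05)

    def test_p95_equals_bruteforce_quantile(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.uniform(0, 2, int(rng.integers(10, 200)))
            est = estimate_micro(x)
            # independent implementation: sorted linear interpolation
            s = np.sort(x)
            h = 0.95 * (s.size - 1)
            lo = int(np.floor(h))
            expected = s[lo] + (h - lo) * (s[min(lo + 1, s.size - 1)] - s[lo])
            assert est.p95 == expected


class TestStates:
    def test_all_rest_day(self):
        probs = probs_from_episodes([("rest", 3600.0, 0.0)])
        assert probs["rest"] == 1.0
        assert probs.sum() == pytest.approx(1.0)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        eps = [("walking", rng.uniform(5, 200), rng.uniform(40, 120)) for _ in range(20)]
        eps += [("active", rng.uniform(5, 200), rng.uniform(0.01, 0.3)) for _ in range(20)]
        assert probs_from_episodes(eps).sum() == pytest.approx(1.0, abs=1e-12)

    def test_two_equal_states(self):
        probs = probs_from_episodes([
            ("walking", 300.0, 100.0),
            ("active", 300.0, 0.05),
        ])
        nz = probs[probs > 0]
        assert len(nz) == 2
        assert np.allclose(nz.to_numpy(), 0.5)

    def test_state_labels(self):
        assert state_label("walking", 45.0, 95.0) == "locomotion_medium_high"
        assert state_label("walking", 5.0, 50.0) == "locomotion_very_short_low"
        assert state_label("active", 120.0, 0.05) == "non_locomotion_long_medium"
        assert state_label("rest", 10.0, 0.0) == "rest"
        assert len(STATE_LABELS) == N_STATES == 25


class TestEntropy:
    def test_reference_values(self):
        p = np.zeros(25)
        p[0] = 1.0
        assert information_entropy(p) == 0.0
        assert information_entropy(np.full(25, 1 / 25)) == pytest.approx(1.0, abs=1e-12)
        p = np.zeros(25)
        p[0] = p[1] = 0.5
        assert information_entropy(p) == pytest.approx(np.log(2) / np.log(25), abs=1e-12)

    def test_merging_states_never_increases_entropy(self):
        rng = np.random.default_rng(2)
        for _ in range(500):
            p = rng.dirichlet(np.ones(25) * rng.uniform(0.2, 3.0))
            h = information_entropy(p)
            i, j = rng.choice(25, size=2, replace=False)
            q = p.copy()
            q[i] += q[j]
            q[j] = 0.0
            assert information_entropy(q) <= h + 1e-12

    def test_validation(self):
        with pytest.raises(ValueError):
            information_entropy([-0.1, 1.1] + [0.0] * 23)
        with pytest.raises(ValueError):
            information_entropy([0.5, 0.4] + [0.0] * 23)


class TestRunPam:
    def test_week_recovery(self, small_week):
        profile = run_pam(small_week)
        assert profile.included
        truth = small_week.truth
        # bout counts per class match the schedule exactly (median over days)
        for i, day in enumerate(profile.days):
            tc = truth.days[i].bout_counts()
            det = {"subthreshold": 0, "short": 0, "medium": 0, "long": 0}
            for b in day.bouts:
                det[b.wb_class] += 1
            assert det == tc
            # steps within 2% of scheduled
            assert day.macro.step_count == pytest.approx(truth.days[i].step_count, rel=0.02)

    def test_micro_availability_follows_bout_counts(self, small_week):
        profile = run_pam(small_week)
        truth = small_week.truth
        n_long = sum(d.bout_counts()["long"] for d in truth.days)
        est = profile.micro[("long", "gait_velocity")]
        assert est.available == (n_long >= 10)
        n_short = sum(d.bout_counts()["short"] for d in truth.days)
        assert profile.micro[("short", "gait_velocity")].available == (n_short >= 10)

    def test_mvpa_matches_schedule_oracle(self, small_week):
        profile = run_pam(small_week)
        truth = small_week.truth
        for i, day in enumerate(profile.days):
            wear = [WearInterval(s, e, w) for s, e, w in truth.days[i].wear_intervals]
            oracle_bouts = [
                _bout_with_steps(b.start, b.end, b.step_times) for b in truth.days[i].bouts
            ]
            left, right = small_week.day(i)
            oracle = compute_macro_day(oracle_bouts, wear, left, right, day_index=i)
            assert abs(day.macro.mvpa_minutes - oracle.mvpa_minutes) <= 1

    def test_insufficient_valid_days_excluded(self):
        ph = phenotype_presets("PD")
        sched = ActivitySchedule([Episode("sedentary", 8 * 3600.0, 2 * 3600.0)])
        week = generate_week_recording([sched, sched], ph, seed=0, fs=FS)
        profile = run_pam(week)
        assert not profile.included
        assert "valid day" in profile.exclusion_reason
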