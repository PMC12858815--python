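"""Tests of stride segmentation, gait events, reconstruction and aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mobgait import IgaConfig, ImuRecording
from mobgait.iga import (
    StrideEvents,
    aggregate_mean_cv,
    asymmetry_index,
    detect_gait_events,
    extract_strides,
    flag_turn_strides,
    pair_consecutive,
    reconstruct_trajectory,
    run_iga,
    segment_strides,
)
from mobgait.iga.segmentation import StrideSegment
from mobgait.synth import generate_gait_test, make_standing_trajectory, trajectory_to_imu

FS = 102.4


def _stationary(duration=5.0, noise=(0.0, 0.0), seed=0):
    return trajectory_to_imu(make_standing_trajectory(duration, FS), noise_sd=noise, seed=seed)


class TestSegmentation:
    def test_stationary_signal_yields_no_segments(self):
        assert segment_strides(_stationary()) == []

    def test_noisy_stationary_signal_yields_no_segments(self):
        assert segment_strides(_stationary(noise=(0.02, 0.5))) == []

    def test_counts_and_boundaries_match_truth(self, straight_walk):
        left, _, truth = straight_walk
        segments = segment_strides(left)
        starts = [s for s in truth.strides if s.foot == "left"]
        assert len(segments) == len(starts) == 20
        for seg, tr in zip(segments, starts):
            assert abs(seg.start - round(tr.start * FS)) <= 5
            assert abs(seg.end - round(tr.end * FS)) <= 5

    def test_segments_ordered_and_disjoint(self, straight_walk):
        left, _, _ = straight_walk
        segments = segment_strides(left)
        for a, b in zip(segments, segments[1:]):
            assert a.end <= b.start

    def test_stride_count_robust_to_noise(self, pd_preset):
        hits = 0
        for seed in range(20):
            left, right, truth = generate_gait_test(
                pd_preset, n_strides_per_pass=6, seed=seed, noise_sd=(0.02, 0.5)
            )
            n = len(extract_strides(left)) + len(extract_strides(right))
            hits += n == truth.count()
        assert hits >= 19


class TestEvents:
    def test_event_order_postcondition(self, straight_walk):
        left, _, _ = straight_walk
        for seg in segment_strides(left):
            ev = detect_gait_events(left, seg)
            assert ev is not None
            assert ev.midstance_start < ev.toe_off < ev.heel_strike < ev.midstance_end

    def test_stance_percentage_recovery(self, pd_preset):
        # noiseless strides generated at the published 63.72% stance
        ph = pd_preset.without_variability()
        left, _, _ = generate_gait_test(ph, n_strides_per_pass=6, n_passes=1,
                                        seed=0, noise_sd=(0, 0))
        for seg in segment_strides(left):
            ev = detect_gait_events(left, seg)
            stride = (ev.midstance_end - ev.midstance_start) / FS
            swing = (ev.heel_strike - ev.toe_off) / FS
            stance_pct = (stride - swing) / stride * 100.0
            assert stance_pct == pytest.approx(63.72, abs=2.0)

    def test_constant_rotation_rejected(self):
        n = int(2 * FS)
        acc = np.tile([0.0, 0.0, 1.0], (n, 1))
        gyr = np.tile([0.0, 100.0, 0.0], (n, 1))
        imu = ImuRecording(acc=acc, gyr=gyr, fs=FS)
        assert detect_gait_events(imu, StrideSegment(0, n)) is None

    def test_out_of_order_events_invalid(self):
        with pytest.raises(ValueError):
            StrideEvents(midstance_start=0, toe_off=50, heel_strike=40, midstance_end=100)


class TestReconstruction:
    def test_stationary_segment_zero_displacement(self):
        imu = _stationary(2.0)
        traj = reconstruct_trajectory(imu, StrideSegment(0, imu.n))
        assert traj.stride_length < 1e-9
        assert abs(traj.max_lift) < 1e-9

    def test_noiseless_length_and_lift(self, straight_walk):
        left, _, truth = straight_walk
        truths = [s for s in truth.strides if s.foot == "left"]
        for seg, tr in zip(segment_strides(left), truths):
            est = reconstruct_trajectory(left, seg)
            assert est.stride_length == pytest.approx(tr.stride_length, rel=0.05)
            assert est.max_lift == pytest.approx(tr.max_sensor_lift, abs=0.01)

    def test_zero_velocity_contract_at_anchors(self, straight_walk):
        left, _, _ = straight_walk
        for seg in segment_strides(left)[:5]:
            est = reconstruct_trajectory(left, seg)
            assert max(est.anchor_speeds) < 1e-6


class TestStrideParams:
    def test_stance_ratio_hand_example(self, straight_walk):
        # stance 0.70 s of a 1.10 s stride -> 63.636...%
        stride_time, swing_time = 1.10, 0.40
        stance_pct = (stride_time - swing_time) / stride_time * 100.0
        assert stance_pct == pytest.approx(63.6363636, abs=1e-6)

    def test_velocity_equals_length_over_time(self, straight_walk):
        left, _, _ = straight_walk
        for rec in extract_strides(left):
            assert rec.gait_velocity == pytest.approx(
                rec.stride_length / rec.stride_time, abs=1e-9
            )


class TestTurnFlags:
    def test_straight_walk_has_no_turns(self, straight_walk):
        left, right, _ = straight_walk
        strides = extract_strides(left) + extract_strides(right)
        flag_turn_strides(strides)
        assert sum(s.is_turn for s in strides) == 0

    def test_flags_equal_ground_truth_turn_set(self, noiseless_pd_test):
        left, right, truth = noiseless_pd_test
        res = run_iga(left, right)
        assert len(res.strides) == truth.count()
        assert int(res.strides.is_turn.sum()) == truth.count(turns=True)
        # flagged strides coincide in time with the labelled turn strides
        det_turn = np.sort(res.strides.loc[res.strides.is_turn, "start_s"].to_numpy())
        true_turn = np.sort([s.start for s in truth.strides if s.is_turn])
        assert np.allclose(det_turn, true_turn, atol=0.1)

    def test_vacuous_threshold_flags_nothing(self, noiseless_pd_test):
        left, right, _ = noiseless_pd_test
        strides = extract_strides(left) + extract_strides(right)
        flag_turn_strides(strides, threshold_deg=361.0)
        assert sum(s.is_turn for s in strides) == 0


class TestAggregates:
    def test_constant_series(self):
        assert aggregate_mean_cv([1.0, 1.0, 1.0]) == (1.0, 0.0)

    def test_hand_computed_cv(self):
        mean, cv = aggregate_mean_cv([0.9, 1.0, 1.1])
        assert mean == pytest.approx(1.0)
        assert cv == pytest.approx(0.1, abs=1e-12)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            aggregate_mean_cv([1.0])

    def test_zero_mean_flags_cv(self):
        mean, cv = aggregate_mean_cv([-1.0, 1.0])
        assert mean == 0.0 and np.isnan(cv)

    @given(st.floats(min_value=0.1, max_value=10.0),
           st.lists(st.floats(min_value=0.5, max_value=2.0), min_size=4, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_scale_equivariance(self, k, values):
        mean, cv = aggregate_mean_cv(values)
        mean_k, cv_k = aggregate_mean_cv([k * v for v in values])
        assert mean_k == pytest.approx(k * mean, rel=1e-9)
        assert cv_k == pytest.approx(cv, rel=1e-6, abs=1e-9)


class TestAsymmetry:
    def test_symmetric_pairs_zero(self):
        assert asymmetry_index([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_single_pair_direct_evaluation(self):
        assert asymmetry_index([1.2], [0.8]) == pytest.approx(20.0, abs=1e-12)

    def test_median_of_pairwise_indices(self):
        assert asymmetry_index([1.05, 1.0], [0.95, 1.0]) == pytest.approx(2.5, abs=1e-12)

    def test_zero_sum_pair_dropped(self):
        assert asymmetry_index([1.0, -1.0], [1.0, 1.0]) == 0.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = rng.integers(1, 40)
            left = rng.uniform(0.1, 2.0, n)
            right = rng.uniform(0.1, 2.0, n)
            # independent brute-force evaluation
            vals = sorted(abs((l - r) / (l + r)) * 100.0 for l, r in zip(left, right))
            m = len(vals)
            expected = vals[m // 2] if m % 2 else 0.5 * (vals[m // 2 - 1] + vals[m // 2])
            assert asymmetry_index(left, right) == pytest.approx(expected, abs=1e-12)

    def test_scale_invariance(self):
        left = [1.1, 0.9, 1.2]
        right = [0.95, 1.05, 1.0]
        assert asymmetry_index(left, right) == pytest.approx(
            asymmetry_index([3 * v for v in left], [3 * v for v in right]), abs=1e-12
        )

    def test_pairing_left_then_next_right(self):
        feet = ["left", "left", "right", "left", "right", "right"]
        starts = [0.0, 1.0, 1.5, 2.0, 2.5, 3.0]
        assert pair_consecutive(feet, starts) == [(1, 2), (3, 4)]


class TestRunIga:
    def test_full_recovery_within_five_percent(self, noiseless_pd_test):
        left, right, truth = noiseless_pd_test
        res = run_iga(left, right)
        tf = truth.frame(include_turns=False)
        for param in ("gait_velocity", "stride_length", "stride_time",
                      "stance_percentage", "max_sensor_lift"):
            assert res.aggregate(param, "mean") == pytest.approx(
                tf[param].mean(), rel=0.05
            )

    def test_empty_recording_flagged_insufficient(self):
        left = _stationary(3.0)
        right = _stationary(3.0)
        right.foot = "right"
        res = run_iga(left, right)
        assert res.insufficient
        assert res.aggregates.isna().all().all()

    def test_degenerate_phenotype_symmetric_and_regular(self, pd_preset):
        ph = pd_preset.without_variability()
        left, right, _ = generate_gait_test(ph, n_strides_per_pass=6, seed=1, noise_sd=(0, 0))
        res = run_iga(left, right)
        assert (res.aggregates["asymmetry_pct"] < 1.0).all()
        assert (res.aggregates["cv"] < 0.02).all()

    def test_mismatched_sampling_rates_rejected(self, noiseless_pd_test):
        left, right, _ = noiseless_pd_test
        other = ImuRecording(acc=right.acc, gyr=right.gyr, fs=51.2, foot="right")
        with pytest.raises(ValueError):
            run_iga(left, other)
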