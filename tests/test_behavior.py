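"""Bout detection, bout assembly, kinematics, and movement events."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from socialphys import (SessionTimeline, assemble_bouts, compute_kinematics,
                        detect_interaction_frames, detect_movement_events)
from socialphys.behavior import CONTACT_TAGS, PositionSeries


def _pos(subj_nose, tgt_nose=(400, 400), tgt_body=(400, 400),
         tgt_tail=(400, 400), n=1, mask=None):
    def tile(p):
        return np.tile(np.asarray(p, float), (n, 1))
    points = {
        "subj_nose": tile(subj_nose), "subj_body": tile(subj_nose),
        "led": tile(subj_nose),
        "tgt_nose": tile(tgt_nose), "tgt_body": tile(tgt_body),
        "tgt_tail": tile(tgt_tail),
    }
    return PositionSeries(points, np.ones(n, bool) if mask is None else mask)


class TestDetection:
    def test_nose_to_body_within_threshold(self):
        pos = _pos((0, 0), tgt_body=(0, 15))
        ind, tags = detect_interaction_frames(pos, threshold=20.0)
        assert ind[0] and CONTACT_TAGS[tags[0]] == "nose-body"

    def test_above_threshold_not_flagged(self):
        pos = _pos((0, 0), tgt_body=(0, 25))
        ind, _ = detect_interaction_frames(pos, threshold=20.0)
        assert not ind[0]

    def test_nearest_part_wins_tag(self):
        # distances nose 30, body 18, tail 12 -> flagged as nose-rear
        pos = _pos((0, 0), tgt_nose=(0, 30), tgt_body=(0, 18), tgt_tail=(0, 12))
        ind, tags = detect_interaction_frames(pos, threshold=20.0)
        assert ind[0] and CONTACT_TAGS[tags[0]] == "nose-rear"

    def test_masked_frames_never_flagged(self):
        pos = _pos((0, 0), tgt_body=(0, 5), n=3,
                   mask=np.array([True, False, True]))
        ind, _ = detect_interaction_frames(pos, threshold=20.0)
        assert list(ind) == [True, False, True]

    def test_all_masked_raises(self):
        pos = _pos((0, 0), n=3, mask=np.zeros(3, bool))
        with pytest.raises(ValueError, match="masked"):
            detect_interaction_frames(pos)

    def test_translation_invariance(self, rng):
        n = 200
        points = {k: rng.uniform(0, 480, (n, 2)) for k in
                  ("subj_nose", "subj_body", "led", "tgt_nose", "tgt_body",
                   "tgt_tail")}
        pos = PositionSeries(points, np.ones(n, bool))
        ind1, _ = detect_interaction_frames(pos, 30.0)
        shifted = PositionSeries({k: v + np.array([13.7, -4.2])
                                  for k, v in points.items()},
                                 np.ones(n, bool))
        ind2, _ = detect_interaction_frames(shifted, 30.0)
        assert np.array_equal(ind1, ind2)

    def test_interaction_time_monotone_in_threshold(self, rng):
        n = 300
        points = {k: rng.uniform(0, 480, (n, 2)) for k in
                  ("subj_nose", "subj_body", "led", "tgt_nose", "tgt_body",
                   "tgt_tail")}
        pos = PositionSeries(points, np.ones(n, bool))
        totals = [detect_interaction_frames(pos, th)[0].sum()
                  for th in (10, 20, 50, 100, 200)]
        assert totals == sorted(totals)


class TestAssembleBouts:
    def test_gap_below_merge_gap_merges(self):
        ind = np.zeros(40, bool)
        ind[10:21] = True
        ind[22:31] = True
        bouts = assemble_bouts(ind, frame_rate=30.0, min_duration=0.0,
                               merge_gap=5 / 30.0)
        assert bouts.n_bouts == 1
        assert tuple(bouts.intervals[0]) == (10, 31)

    def test_short_run_dropped(self):
        ind = np.zeros(40, bool)
        ind[5:7] = True  # 2 frames < 0.2 s at 30 Hz (6 frames)
        bouts = assemble_bouts(ind, frame_rate=30.0, min_duration=0.2,
                               merge_gap=0.0)
        assert bouts.n_bouts == 0

    @given(st.lists(st.booleans(), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_flag_count_conserved_without_cleaning(self, flags):
        ind = np.array(flags, bool)
        bouts = assemble_bouts(ind, frame_rate=30.0, min_duration=0.0,
                               merge_gap=0.0)
        assert bouts.indicator.sum() == ind.sum()
        assert np.array_equal(bouts.indicator, ind)

    def test_bout_lengths_bounded_by_flag_count_plus_gaps(self, rng):
        ind = rng.random(500) < 0.3
        bouts = assemble_bouts(ind, frame_rate=30.0, min_duration=0.2,
                               merge_gap=0.0)
        assert bouts.indicator.sum() <= ind.sum()


class TestKinematics:
    def _series(self, led, timeline):
        n = led.shape[0]
        points = {k: led.copy() for k in ("subj_nose", "subj_body", "led",
                                          "tgt_nose", "tgt_body", "tgt_tail")}
        return PositionSeries(points, np.ones(n, bool))

    def test_constant_velocity_speed(self):
        tl = SessionTimeline.regular(10.0, 30.0)
        # (0,0) -> (30,40) mm over 1 s, then continuing: |v| = 50 mm/s
        led = np.outer(tl.t, [30.0, 40.0])
        kin = compute_kinematics(self._series(led, tl), tl, median_width=1)
        assert np.allclose(kin.speed, 50.0)
        assert np.allclose(kin.angular_speed, 0.0, atol=1e-9)

    def test_stationary_led_zero_speed_masked(self):
        tl = SessionTimeline.regular(5.0, 30.0)
        led = np.full((tl.n_frames, 2), 100.0)
        kin = compute_kinematics(self._series(led, tl), tl, median_width=1)
        assert np.allclose(kin.speed, 0.0)
        assert np.allclose(kin.angular_speed, 0.0)
        assert kin.low_speed_mask.all()

    def test_circular_motion_angular_speed(self):
        tl = SessionTimeline.regular(30.0, 30.0)
        omega = np.radians(60.0)  # 60 deg/s
        r = 100.0
        led = r * np.stack([np.cos(omega * tl.t), np.sin(omega * tl.t)], axis=1)
        kin = compute_kinematics(self._series(led, tl), tl, median_width=1)
        interior = slice(5, -5)
        assert np.allclose(kin.angular_speed[interior], 60.0, rtol=0.05)

    def test_too_few_valid_frames_raises(self):
        tl = SessionTimeline.regular(1.0, 30.0)
        led = np.zeros((tl.n_frames, 2))
        pos = self._series(led, tl)
        pos.mask[:] = False
        pos.mask[0] = True
        with pytest.raises(ValueError, match="3 valid frames"):
            compute_kinematics(pos, tl)


class TestMovementEvents:
    def _kin(self, speed):
        from socialphys.behavior import KinematicsSeries
        return KinematicsSeries(np.asarray(speed, float),
                                np.zeros(len(speed)),
                                np.zeros(len(speed), bool))

    def test_step_input_single_onset(self):
        speed = np.r_[np.zeros(300), np.full(300, 100.0)]
        ev = detect_movement_events(self._kin(speed), 30.0, on_thresh=50,
                                    off_thresh=20, refractory=1.0)
        assert list(ev.locomotion_onsets) == [300]
        assert ev.locomotion_offsets.size == 0

    def test_subthreshold_oscillation_no_events(self):
        t = np.arange(600) / 30.0
        speed = 10 + 5 * np.sin(2 * np.pi * t)
        ev = detect_movement_events(self._kin(speed), 30.0, on_thresh=50,
                                    off_thresh=20, refractory=1.0)
        assert ev.locomotion_onsets.size == 0
        assert ev.locomotion_offsets.size == 0

    def test_square_wave_event_count_matches_enumeration(self):
        # 5 s low / 5 s high alternation: every up-crossing after >=1 s low
        # is an onset, every down-crossing after >=1 s high an offset
        frame_rate = 30.0
        half = int(5 * frame_rate)
        speed = np.tile(np.r_[np.zeros(half), np.full(half, 100.0)], 6)
        ev = detect_movement_events(self._kin(speed), frame_rate,
                                    on_thresh=50, off_thresh=20,
                                    refractory=1.0)
        assert ev.locomotion_onsets.size == 6
        assert ev.locomotion_offsets.size == 5  # last high period ends the trace

    def test_hysteresis_requires_ordered_thresholds(self):
        with pytest.raises(ValueError, match="hysteresis"):
            detect_movement_events(self._kin(np.zeros(10)), 30.0,
                                   on_thresh=10, off_thresh=20)


class TestBoutRecovery:
    def test_detect_assemble_recovers_planted_bouts(self, default_session):
        """Frame-level Jaccard >= 0.95 between truth and detected bouts."""
        s = default_session
        ind, tags = detect_interaction_frames(s.positions, 20.0)
        det = assemble_bouts(ind, s.timeline.frame_rate, tag_idx=tags)
        truth = np.zeros(s.timeline.n_frames, bool)
        for a, b in s.truth.bout_intervals:
            truth[a:b] = True
        jac = (truth & det.indicator).sum() / (truth | det.indicator).sum()
        assert jac >= 0.95
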