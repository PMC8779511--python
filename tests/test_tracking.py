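import numpy as np
import pytest

from thermocomfort.core import BoundingBox, Detection, PersonCategory
from thermocomfort.tracking import (
    LabelledBox,
    MotCounts,
    MultiObjectTracker,
    Track,
    TrackerConfig,
    TrackState,
    compute_mota,
    evaluate_tracking,
    vote_category,
    _KalmanBoxFilter,
)

from mot_oracle import brute_force_mot

CAT = PersonCategory.LONG_SIT


def det(frame, x, y, w=50, h=120, category=CAT):
    return Detection(frame, BoundingBox(x, y, w, h), category, 0.9)


def run_frames(tracker, detections_by_frame):
    for f, dets in enumerate(detections_by_frame):
        tracker.step(f, dets)
    return tracker


class TestKalman:
    def test_tracks_constant_velocity(self):
        kf = _KalmanBoxFilter(BoundingBox(100, 100, 50, 120))
        for i in range(1, 10):
            kf.predict()
            kf.update(BoundingBox(100 + 3 * i, 100, 50, 120))
        predicted = kf.predict()
        expected = BoundingBox(100 + 30, 100, 50, 120)
        assert predicted.iou(expected) > 0.9


class TestAssociation:
    def test_overlapping_detection_keeps_track_id(self):
        tracker = MultiObjectTracker()
        run_frames(tracker, [[det(0, 100, 100)], [det(1, 102, 101)], [det(2, 104, 102)]])
        assert len(tracker.tracks) == 1
        assert tracker.tracks[0].is_confirmed
        assert tracker.tracks[0].track_id == 1

    def test_non_consecutive_frames_rejected(self):
        tracker = MultiObjectTracker()
        tracker.step(0, [det(0, 100, 100)])
        with pytest.raises(ValueError, match="non-consecutive"):
            tracker.step(2, [det(2, 100, 100)])

    def test_wrong_frame_index_in_detection_rejected(self):
        tracker = MultiObjectTracker()
        with pytest.raises(ValueError, match="frame_index"):
            tracker.step(0, [det(3, 100, 100)])

    def test_track_ids_strictly_increase(self):
        tracker = MultiObjectTracker()
        frames = [[det(0, 0, 0), det(0, 200, 0)], [det(1, 0, 0), det(1, 200, 0)]]
        run_frames(tracker, frames)
        ids = [t.track_id for t in tracker.history]
        assert ids == sorted(ids) and len(set(ids)) == len(ids)

    def test_appearance_hook_breaks_iou_tie(self):
        # two detections equally overlapping one track; the hook prefers one
        hook_calls = []

        def hook(detection, track):
            hook_calls.append(detection)
            return 0.0 if detection.box.x < 150 else 1.0

        cfg = TrackerConfig(appearance_hook=hook, appearance_weight=0.5)
        tracker = MultiObjectTracker(cfg)
        run_frames(tracker, [[det(0, 100, 100)], [det(1, 100, 100)]])
        assert hook_calls  # the hook participated in association


class TestLifecycle:
    def test_short_lived_false_positive_never_confirmed(self):
        tracker = MultiObjectTracker()
        frames = [[det(0, 300, 50)], [], [], []]
        run_frames(tracker, frames)
        assert tracker.confirmed_tracks == []
        assert tracker.ever_confirmed_tracks == []

    def test_two_frame_blip_never_confirmed(self):
        tracker = MultiObjectTracker(TrackerConfig(n_init=3))
        run_frames(tracker, [[det(0, 300, 50)], [det(1, 300, 50)], [], []])
        assert tracker.ever_confirmed_tracks == []

    def test_gap_up_to_max_age_preserves_id(self):
        cfg = TrackerConfig(max_age=5)
        tracker = MultiObjectTracker(cfg)
        frames = [[det(f, 100 + 2 * f, 100)] for f in range(4)]
        frames += [[] for _ in range(5)]  # gap == max_age
        f0 = len(frames)
        frames += [[det(f0 + i, 100 + 2 * (f0 + i), 100)] for i in range(3)]
        run_frames(tracker, frames)
        confirmed = tracker.confirmed_tracks
        assert len(confirmed) == 1 and confirmed[0].track_id == 1

    def test_deleted_after_max_age_exceeded(self):
        cfg = TrackerConfig(max_age=5)
        tracker = MultiObjectTracker(cfg)
        frames = [[det(f, 100, 100)] for f in range(4)] + [[] for _ in range(6)]
        run_frames(tracker, frames)
        assert tracker.tracks == []  # deleted
        assert tracker.ever_confirmed_tracks[0].state is TrackState.DELETED


class TestVoteCategory:
    def _track_with_history(self, history):
        t = Track(track_id=1, kf=_KalmanBoxFilter(BoundingBox(0, 0, 10, 10)))
        t.category_history = list(enumerate(history))
        return t

    def test_strict_majority(self):
        hist = [PersonCategory.LONG_SIT] * 180 + [PersonCategory.OCL_SIT] * 30
        t = self._track_with_history(hist)
        assert vote_category(t, window=210) is PersonCategory.LONG_SIT

    def test_single_element(self):
        t = self._track_with_history([PersonCategory.SHORT_STAND])
        assert vote_category(t, window=63) is PersonCategory.SHORT_STAND

    def test_tie_prefers_previous_vote(self):
        hist = [PersonCategory.LONG_SIT] * 30 + [PersonCategory.SHORT_SIT] * 30
        t = self._track_with_history(hist)
        t.last_vote = PersonCategory.LONG_SIT
        assert vote_category(t, window=60) is PersonCategory.LONG_SIT

    def test_tie_prefers_non_occluded(self):
        hist = [PersonCategory.OCL_SIT] * 30 + [PersonCategory.LONG_SIT] * 30
        t = self._track_with_history(hist)
        assert vote_category(t, window=60) is PersonCategory.LONG_SIT

    def test_window_restricts_history(self):
        hist = [PersonCategory.LONG_SIT] * 100 + [PersonCategory.SHORT_SIT] * 10
        t = self._track_with_history(hist)
        assert vote_category(t, window=10) is PersonCategory.SHORT_SIT

    def test_empty_history_rejected(self):
        t = Track(track_id=1, kf=_KalmanBoxFilter(BoundingBox(0, 0, 10, 10)))
        with pytest.raises(ValueError, match="empty"):
            vote_category(t, window=63)


class TestMota:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (MotCounts(44077, 206, 16, 0), 99.5),
            (MotCounts(100, 0, 0, 0), 100.0),
            (MotCounts(100, 10, 5, 1), 84.0),
        ],
    )
    def test_arithmetic(self, counts, expected):
        assert round(compute_mota(counts), 1) == expected

    def test_zero_gt_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            compute_mota(MotCounts(0, 0, 0, 0))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            MotCounts(10, 11, 0, 0)


class TestEvaluateTracking:
    def _stream(self, spec):
        return [LabelledBox(f, i, BoundingBox(x, y, 40, 90)) for f, i, x, y in spec]

    def test_self_match(self):
        gt = self._stream([(f, 1, 100 + f, 50) for f in range(10)])
        counts = evaluate_tracking(gt, gt)
        assert counts == MotCounts(10, 0, 0, 0)

    def test_all_missed(self):
        gt = self._stream([(f, 1, 100, 50) for f in range(5)])
        counts = evaluate_tracking(gt, [])
        assert counts == MotCounts(5, 5, 0, 0)

    def test_forced_id_swap_counts_one_switch(self):
        # two crossing objects; hypothesis ids swap at the crossing frame
        gt, hyp = [], []
        for f in range(10):
            a = BoundingBox(50 + 20 * f, 50, 40, 90)
            b = BoundingBox(230 - 20 * f, 50, 40, 90)
            gt += [LabelledBox(f, 1, a), LabelledBox(f, 2, b)]
            if f < 5:
                hyp += [LabelledBox(f, 11, a), LabelledBox(f, 12, b)]
            else:
                hyp += [LabelledBox(f, 12, a), LabelledBox(f, 11, b)]
        counts = evaluate_tracking(gt, hyp)
        assert counts.idsw == 2  # both identities change partner once
        assert counts.fn == 0 and counts.fp == 0

    def test_agrees_with_brute_force_oracle_on_random_scenarios(self):
        rng = np.random.default_rng(42)
        for trial in range(50):
            n_obj = rng.integers(1, 4)
            n_frames = int(rng.integers(3, 8))
            gt_by_frame, hyp_by_frame = {}, {}
            gt_list, hyp_list = [], []
            pos = rng.uniform(0, 300, size=(n_obj, 2))
            for f in range(n_frames):
                pos += rng.uniform(-10, 10, size=pos.shape)
                gts, hyps = [], []
                for i in range(n_obj):
                    box = BoundingBox(pos[i, 0], pos[i, 1], 40, 90)
                    gts.append((i + 1, box))
                    if rng.uniform() < 0.85:  # random misses
                        jitter = rng.uniform(-6, 6, size=2)
                        hbox = BoundingBox(
                            pos[i, 0] + jitter[0], pos[i, 1] + jitter[1], 40, 90
                        )
                        # occasional wrong identity
                        hid = int(rng.integers(1, n_obj + 1)) if rng.uniform() < 0.15 else i + 1
                        hyps.append((100 + hid, hbox))
                    if rng.uniform() < 0.1:  # random clutter
                        hyps.append(
                            (200 + f, BoundingBox(*rng.uniform(0, 300, 2), 40, 90))
                        )
                # drop duplicate hypothesis ids within a frame
                seen, clean = set(), []
                for hid, box in hyps:
                    if hid not in seen:
                        seen.add(hid)
                        clean.append((hid, box))
                gt_by_frame[f] = gts
                hyp_by_frame[f] = clean
                gt_list += [LabelledBox(f, i, b) for i, b in gts]
                hyp_list += [LabelledBox(f, i, b) for i, b in clean]
            ours = evaluate_tracking(gt_list, hyp_list)
            oracle = brute_force_mot(gt_by_frame, hyp_by_frame)
            assert (ours.gt, ours.fn, ours.fp, ours.idsw) == oracle, f"trial {trial}"
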