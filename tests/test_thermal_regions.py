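import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermocomfort.core import BoundingBox, Keypoint, PipelineConfig, SleeveStatus, ThermalFrame
from thermocomfort.thermal_regions import (
    InsufficientSamplesError,
    RegionSamples,
    accumulate_samples,
    assign_skeleton,
    background_temperature,
    background_temperature_window,
    keypoint_accuracy,
    locate_regions,
    summarize,
)
from thermocomfort.tracking import Track, _KalmanBoxFilter


def full_skeleton(score=0.9):
    pts = {
        "nose": (50, 10),
        "left_shoulder": (40, 25),
        "right_shoulder": (60, 25),
        "left_elbow": (35, 45),
        "right_elbow": (65, 45),
        "left_wrist": (33, 62),
        "right_wrist": (67, 62),
    }
    return [Keypoint(n, u, v, score) for n, (u, v) in pts.items()]


class TestLocateRegions:
    def test_short_sleeves(self):
        skin, clothes = locate_regions(full_skeleton(), SleeveStatus.SHORT, 0.6)
        assert skin == {(50, 10), (34.0, 53.5), (66.0, 53.5)}  # nose + forearm midpoints
        assert clothes == {(40, 25), (60, 25)}  # shoulders only

    def test_long_sleeves(self):
        skin, clothes = locate_regions(full_skeleton(), SleeveStatus.LONG, 0.6)
        assert skin == {(50, 10)}
        assert clothes == {(40, 25), (60, 25), (35, 45), (65, 45)}

    def test_occluded_uses_conservative_subset(self):
        skin, clothes = locate_regions(full_skeleton(), SleeveStatus.OCCLUDED, 0.6)
        assert skin == {(50, 10)}
        assert clothes == {(40, 25), (60, 25)}

    def test_low_confidence_wrist_drops_that_side_only(self):
        skel = [
            k if k.name != "left_wrist" else Keypoint("left_wrist", k.u, k.v, 0.4)
            for k in full_skeleton()
        ]
        skin, _ = locate_regions(skel, SleeveStatus.SHORT, 0.6)
        assert (34.0, 53.5) not in skin  # left midpoint gone
        assert (66.0, 53.5) in skin  # right side unaffected
        assert (50, 10) in skin

    def test_containment_between_sleeve_statuses(self):
        skel = full_skeleton()
        s_short, c_short = locate_regions(skel, SleeveStatus.SHORT, 0.6)
        s_long, c_long = locate_regions(skel, SleeveStatus.LONG, 0.6)
        s_ocl, c_ocl = locate_regions(skel, SleeveStatus.OCCLUDED, 0.6)
        assert s_short >= s_long >= s_ocl
        assert c_long >= c_short == c_ocl

    @settings(max_examples=50, deadline=None)
    @given(
        scores=st.lists(st.floats(0, 1), min_size=7, max_size=7),
        t1=st.floats(0.05, 0.95),
        t2=st.floats(0.05, 0.95),
        status=st.sampled_from(list(SleeveStatus)),
    )
    def test_threshold_monotone_shrinkage(self, scores, t1, t2, status):
        skel = [
            Keypoint(k.name, k.u, k.v, s) for k, s in zip(full_skeleton(), scores)
        ]
        lo, hi = min(t1, t2), max(t1, t2)
        skin_lo, clothes_lo = locate_regions(skel, status, lo)
        skin_hi, clothes_hi = locate_regions(skel, status, hi)
        assert skin_hi <= skin_lo
        assert clothes_hi <= clothes_lo
        # nothing below threshold contributes
        valid = {k.name for k in skel if k.score >= hi}
        if "nose" not in valid:
            assert (50, 10) not in skin_hi


class TestAccumulateSamples:
    def _scene(self, n_frames, sleeve, temps=(34.5, 33.0, 25.0), occlude_nose=False):
        """Tiny handmade scene: constant box, constant keypoints."""
        skin_t, clothes_t, bg = temps
        values = np.full((100, 120), bg)
        skel = full_skeleton()
        if occlude_nose:
            skel = [
                k if k.name != "nose" else Keypoint("nose", k.u, k.v, 0.1) for k in skel
            ]
        skin, clothes = locate_regions(skel, sleeve, 0.6)
        for u, v in skin:
            values[int(round(v)), int(round(u))] = skin_t
        for u, v in clothes:
            values[int(round(v)), int(round(u))] = clothes_t
        frames = {f: ThermalFrame(values) for f in range(n_frames)}
        skeletons = {f: [skel] for f in range(n_frames)}
        track = Track(track_id=1, kf=_KalmanBoxFilter(BoundingBox(20, 0, 60, 80)))
        track.trajectory = [(f, BoundingBox(20, 0, 60, 80)) for f in range(n_frames)]
        return track, skeletons, frames

    def test_long_sleeve_counts(self, config):
        track, skeletons, frames = self._scene(100, SleeveStatus.LONG)
        samples = accumulate_samples(
            track, skeletons, frames, config, sleeve_status=SleeveStatus.LONG
        )
        assert samples.n_skin == 100  # 1 nose per frame
        assert samples.n_clothes == 400  # 2 shoulders + 2 elbows per frame

    def test_fully_visible_short_sleeve_counts(self, config):
        track, skeletons, frames = self._scene(50, SleeveStatus.SHORT)
        samples = accumulate_samples(
            track, skeletons, frames, config, sleeve_status=SleeveStatus.SHORT
        )
        assert samples.n_skin == 50 * 3 and samples.n_clothes == 50 * 2

    def test_occluded_nose_yields_empty_skin_set(self, config):
        track, skeletons, frames = self._scene(20, SleeveStatus.LONG, occlude_nose=True)
        samples = accumulate_samples(
            track, skeletons, frames, config, sleeve_status=SleeveStatus.LONG
        )
        assert samples.n_skin == 0
        with pytest.raises(InsufficientSamplesError, match="skin"):
            summarize(samples, to=25.0)

    def test_temperatures_read_from_the_right_pixels(self, config):
        track, skeletons, frames = self._scene(10, SleeveStatus.SHORT)
        samples = accumulate_samples(
            track, skeletons, frames, config, sleeve_status=SleeveStatus.SHORT
        )
        summary = summarize(samples, to=25.0)
        assert summary.ts == pytest.approx(34.5)
        assert summary.tc == pytest.approx(33.0)

    def test_empty_window_rejected(self, config):
        track, skeletons, frames = self._scene(5, SleeveStatus.LONG)
        with pytest.raises(ValueError, match="at least one frame"):
            accumulate_samples(track, skeletons, frames, config, frames=[],
                               sleeve_status=SleeveStatus.LONG)


def test_assign_skeleton_prefers_max_overlap():
    near = full_skeleton()
    far = [Keypoint(k.name, k.u + 200, k.v, k.score) for k in near]
    box = BoundingBox(20, 0, 60, 80)
    assert assign_skeleton([far, near], box) is near
    assert assign_skeleton([far], BoundingBox(500, 500, 10, 10)) is None


class TestSummarize:
    def test_two_point_mean(self):
        samples = RegionSamples(
            skin_points=[(0, 0, 0, 34.0), (0, 1, 1, 35.0)],
            clothes_points=[(0, 2, 2, 33.0)],
            window_frames=1,
        )
        s = summarize(samples, to=25.0)
        assert s.ts == pytest.approx(34.5)
        assert s.tc == pytest.approx(33.0)
        assert s.to == 25.0

    def test_order_invariance_and_bounds(self):
        rng = np.random.default_rng(0)
        temps = rng.uniform(30, 36, 50)
        pts = [(0, i, i, t) for i, t in enumerate(temps)]
        clothes = [(0, 0, 0, 33.0)]
        a = summarize(RegionSamples(pts, clothes, 1), to=25.0)
        b = summarize(RegionSamples(pts[::-1], clothes, 1), to=25.0)
        assert a.ts == pytest.approx(b.ts)
        assert temps.min() <= a.ts <= temps.max()

    def test_empty_clothes_region_named_in_error(self):
        samples = RegionSamples([(0, 0, 0, 34.0)], [], 1)
        with pytest.raises(InsufficientSamplesError, match="clothes"):
            summarize(samples, to=25.0)


class TestBackgroundTemperature:
    def test_uniform_field(self):
        frame = ThermalFrame(np.full((20, 20), 25.0))
        assert background_temperature(frame, [BoundingBox(5, 5, 5, 5)]) == 25.0

    def test_box_pixels_excluded(self):
        values = np.full((10, 10), 20.0)
        values[2:7, 2:7] = 35.0
        frame = ThermalFrame(values)
        assert background_temperature(frame, [BoundingBox(2, 2, 5, 5)]) == pytest.approx(20.0)

    def test_full_coverage_rejected(self):
        frame = ThermalFrame(np.full((5, 5), 20.0))
        with pytest.raises(ValueError, match="no background"):
            background_temperature(frame, [BoundingBox(0, 0, 5, 5)])

    def test_window_average(self):
        f1 = ThermalFrame(np.full((5, 5), 20.0))
        f2 = ThermalFrame(np.full((5, 5), 22.0))
        to = background_temperature_window([f1, f2], [[], []])
        assert to == pytest.approx(21.0)


def test_keypoint_accuracy_arithmetic():
    assert round(keypoint_accuracy(187, 4901), 1) == 96.2
    assert keypoint_accuracy(0, 100) == 100.0
    with pytest.raises(ValueError):
        keypoint_accuracy(5, 4)
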