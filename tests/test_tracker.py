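import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apextrack.relearn import RelearnConfig, reset
from apextrack.synthetic_data import SceneSpec, generate_video
from apextrack.tracker import (CandidateSet, TrackerConfig, TrackerState,
                               crop_search_range, locate_center,
                               remove_outliers, select_search_range,
                               threshold_map, track_frame, track_video)


class TestCropSearchRange:
    frame = np.zeros((480, 640, 3), dtype=np.uint8)

    def test_interior_window_position_and_size(self):
        crop, offset = crop_search_range(self.frame, (300, 240), 50)
        assert crop.shape == (101, 101, 3)
        assert offset == (250, 190)

    def test_border_window_shifted_inward(self):
        crop, offset = crop_search_range(self.frame, (10, 10), 50)
        assert crop.shape == (101, 101, 3)
        assert offset == (0, 0)

    def test_first_frame_uses_whole_frame(self):
        crop, offset = crop_search_range(self.frame, None, 50)
        assert crop.shape == self.frame.shape and offset == (0, 0)

    def test_oversized_range_falls_back_to_whole_frame(self):
        with pytest.warns(UserWarning, match="whole frame"):
            crop, offset = crop_search_range(self.frame, (320, 240), 400)
        assert crop.shape == self.frame.shape and offset == (0, 0)

    @settings(max_examples=50, derandomize=True)
    @given(cx=st.integers(0, 639), cy=st.integers(0, 479),
           r1=st.integers(1, 239))
    def test_size_always_exact_when_window_fits(self, cx, cy, r1):
        crop, (ox, oy) = crop_search_range(self.frame, (cx, cy), r1)
        side = 2 * r1 + 1
        assert crop.shape == (side, side, 3)
        assert 0 <= ox <= 640 - side and 0 <= oy <= 480 - side


class TestThresholdMap:
    def test_boundary_is_inclusive(self):
        p = np.array([[0.8, 0.75, 0.7]])
        assert threshold_map(p, 0.75).tolist() == [[1, 1, 0]]

    def test_degenerate_maps(self):
        assert threshold_map(np.zeros((3, 3)), 0.75).sum() == 0
        assert threshold_map(np.ones((3, 3)), 0.75).sum() == 9

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_map(np.zeros((2, 2)), 1.5)


def brute_force_filter(points, prev, r2, r3):
    """Plain-python reimplementation of the two-stage outlier filter."""
    kept = [p for p in points
            if math.hypot(p[0] - prev[0], p[1] - prev[1]) <= r2]
    if not kept:
        return []
    xs = sorted(p[0] for p in kept)
    ys = sorted(p[1] for p in kept)

    def median(v):
        n = len(v)
        return v[n // 2] if n % 2 else (v[n // 2 - 1] + v[n // 2]) / 2

    mx, my = median(xs), median(ys)
    return [p for p in kept if abs(p[0] - mx) <= r3 and abs(p[1] - my) <= r3]


class TestRemoveOutliers:
    def test_distance_gate(self):
        cand = CandidateSet([(1, 1), (40, 0)])
        out = remove_outliers(cand, (0, 0), 30, 15)
        assert out.points.tolist() == [[1, 1]]

    def test_median_gate(self):
        pts = [(0, 5), (1, 5), (2, 5), (100, 5)]
        out = remove_outliers(CandidateSet(pts), (1, 5), 200, 15)
        # median x = 1.5; the point at x=100 deviates by 98.5 > 15
        assert out.points[:, 0].tolist() == [0, 1, 2]

    def test_single_inlier_survives(self):
        out = remove_outliers(CandidateSet([(3, 4)]), (0, 0), 30, 15)
        assert out.points.tolist() == [[3, 4]]

    def test_empty_in_empty_out(self):
        out = remove_outliers(CandidateSet([]), (0, 0), 30, 15)
        assert len(out) == 0

    def test_all_beyond_r2_gives_empty_set(self):
        out = remove_outliers(CandidateSet([(50, 50)]), (0, 0), 30, 15)
        assert len(out) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.integers(0, 60, size=(int(rng.integers(0, 25)), 2))
        prev = tuple(rng.integers(0, 60, 2).tolist())
        r2 = float(rng.uniform(1, 50))
        r3 = float(rng.uniform(1, 25))
        out = remove_outliers(CandidateSet(pts.astype(float)), prev, r2, r3)
        expected = brute_force_filter(pts.tolist(), prev, r2, r3)
        assert sorted(map(tuple, out.points.tolist())) == \
            sorted(map(tuple, expected))

    @pytest.mark.parametrize("seed", range(5))
    def test_output_is_subset_within_r2(self, seed):
        """Filtering only removes points, and every survivor obeys the R2
        gate (so re-applying the distance gate alone changes nothing).
        The median gate is deliberately one-pass: re-applying it can drop
        further points because the median moves with the survivors."""
        rng = np.random.default_rng(100 + seed)
        pts = rng.uniform(0, 60, size=(20, 2))
        prev = (30.0, 30.0)
        out = remove_outliers(CandidateSet(pts), prev, 20, 10)
        in_set = {tuple(p) for p in pts.tolist()}
        assert all(tuple(p) in in_set for p in out.points.tolist())
        d = np.hypot(out.points[:, 0] - prev[0], out.points[:, 1] - prev[1])
        assert (d <= 20).all()


class TestLocateCenter:
    def test_mean_of_candidates(self):
        assert locate_center(CandidateSet([(0, 0), (2, 2)])) == (1.0, 1.0)

    def test_singleton(self):
        assert locate_center(CandidateSet([(5, 7)])) == (5.0, 7.0)

    def test_empty_returns_none(self):
        assert locate_center(CandidateSet([])) is None


class TestSelectSearchRange:
    config = TrackerConfig()

    @pytest.mark.parametrize("bench,r1", [
        (0.02, 200), (0.30, 50), (0.10, 100),
        (0.04, 100), (0.17, 100),   # bounds themselves are the middle band
    ])
    def test_bands(self, bench, r1):
        assert select_search_range(bench, self.config) == r1

    def test_invalid_time_rejected(self):
        with pytest.raises(ValueError):
            select_search_range(0.0, self.config)


class TestTrackerConfig:
    def test_r3_defaults_to_half_r2(self):
        assert TrackerConfig(r2=30.0).r3 == 15.0
        assert TrackerConfig(r2=8.0).r3 == 4.0

    def test_validation(self):
        with pytest.raises(ValueError):
            TrackerConfig(t_m=1.5)
        with pytest.raises(ValueError):
            TrackerConfig(box_side=4)


@pytest.fixture(scope="module")
def clean_video():
    from apextrack.benchmarks import sample_reduced_specs
    return generate_video(sample_reduced_specs(1, 1, n_frames=60, group=3)[0])


@pytest.fixture(scope="module")
def reduced_config():
    from apextrack.benchmarks import reduced_tracker_config
    return reduced_tracker_config()


class TestTrackFrame:
    def test_detects_blob_near_previous_center(self, pretrained, clean_video,
                                               reduced_config):
        params, anchor = reset(pretrained.params_)
        state = TrackerState(params=params, anchor=anchor,
                             prev_center=clean_video.annotations[0].center)
        rec = track_frame(state, clean_video.sequence.frames[0],
                          reduced_config, RelearnConfig())
        truth = clean_video.annotations[0].center
        assert not rec.lost
        assert math.hypot(rec.x - truth[0], rec.y - truth[1]) <= 5.0

    def test_background_frame_marks_lost_and_keeps_center(
            self, pretrained, clean_video, reduced_config):
        spec = clean_video.spec
        bg = np.zeros_like(clean_video.sequence.frames[0])
        bg[:] = spec.background_color
        params, anchor = reset(pretrained.params_)
        state = TrackerState(params=params, anchor=anchor,
                             prev_center=(24.0, 29.0))
        rec = track_frame(state, bg, reduced_config, relearn_enabled=False)
        assert rec.lost
        assert state.prev_center == (24.0, 29.0)
        assert (rec.x, rec.y) == (24.0, 29.0)

    def test_identical_frames_identical_predictions(self, pretrained,
                                                    clean_video,
                                                    reduced_config):
        frame = clean_video.sequence.frames[10]
        results = []
        for _ in range(2):
            params, anchor = reset(pretrained.params_)
            state = TrackerState(params=params, anchor=anchor,
                                 prev_center=clean_video.annotations[10].center)
            rec = track_frame(state, frame, reduced_config,
                              relearn_enabled=False)
            results.append((rec.x, rec.y))
        assert results[0] == results[1]


class TestTrackVideo:
    def test_one_record_per_frame_in_order(self, pretrained, clean_video,
                                           reduced_config):
        result = track_video(clean_video.sequence, pretrained.params_,
                             config=reduced_config)
        assert len(result) == len(clean_video.sequence)
        assert [r.frame_index for r in result.records] == list(range(60))

    def test_reproducible(self, pretrained, clean_video, reduced_config):
        a = track_video(clean_video.sequence, pretrained.params_,
                        config=reduced_config)
        b = track_video(clean_video.sequence, pretrained.params_,
                        config=reduced_config)
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.lost, b.lost)

    def test_initial_box_selects_among_two_apices(self, pretrained,
                                                  reduced_config):
        left = SceneSpec.reduced(seed=21, n_frames=40, center=(13.0, 29.0),
                                 semi_axes=(3.0, 2.0), growth=0.02)
        right = SceneSpec.reduced(seed=22, n_frames=40, center=(35.0, 29.0),
                                  semi_axes=(3.0, 2.0), growth=0.02,
                                  phase=2.0)
        lv, rv = generate_video(left), generate_video(right)
        frames = np.maximum(lv.sequence.frames, rv.sequence.frames)
        x0, y0 = lv.annotations[0].center
        result = track_video(frames, pretrained.params_, config=reduced_config,
                             relearn_config=RelearnConfig(),
                             initial_box=(int(x0) - 3, int(y0) - 3, 7, 7))
        assert result.n_lost == 0
        assert (result.centers[:, 0] < 24).all()   # stays on the left apex

    def test_trajectory_csv_round_trip(self, pretrained, clean_video,
                                       reduced_config, tmp_path):
        from apextrack.tracker import TrackResult
        result = track_video(clean_video.sequence, pretrained.params_,
                             config=reduced_config)
        path = tmp_path / "traj.csv"
        result.save_csv(path)
        loaded = TrackResult.load_csv(path)
        assert np.allclose(loaded.centers, result.centers)
        assert np.array_equal(loaded.lost, result.lost)


class TestApexTracker:
    def test_estimator_with_prefitted_segmenter(self, pretrained, clean_video):
        from apextrack.tracker import ApexTracker
        tracker = ApexTracker(segmenter=pretrained, r1=8, r2=5.0, box_side=5)
        tracker.fit(None)
        result = tracker.predict(clean_video.sequence)
        assert len(result) == len(clean_video.sequence)
        assert result.n_lost == 0

    def test_sklearn_clone(self):
        from sklearn.base import clone
        from apextrack.tracker import ApexTracker
        t = ApexTracker(r1=8, alpha=0.8)
        assert clone(t).get_params()["alpha"] == 0.8
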