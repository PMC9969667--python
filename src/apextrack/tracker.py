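"""Per-frame apex tracking: crop, segment, threshold, filter, localize.

Each frame is processed by the pipeline

    crop a (2*R1+1)-pixel search range around the previous apex center
    -> segmentation network -> probability map
    -> threshold at T_m -> candidate pixels (mapped to full-frame coords)
    -> outlier removal (R2 distance gate, then R3 median-deviation gate)
    -> apex center = mean of the surviving candidate coordinates

The first frame is segmented whole (no previous center exists yet).  If a
frame yields no candidates it is flagged "lost" and the previous center
is retained, so a single failure does not corrupt subsequent frames.
Model Update (see :mod:`apextrack.relearn`) is invoked when the suspicion
score exceeds its trigger threshold.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .dataset_io import FrameSequence, make_mask
from .relearn import RelearnConfig, compute_suspicion, relearn_on_frame, reset
from .segmentation_model import UNetSegmenter, infer

__all__ = [
    "TrackerConfig", "TrackerState", "CandidateSet", "FrameRecord",
    "TrackResult", "crop_search_range", "threshold_map", "remove_outliers",
    "locate_center", "select_search_range", "track_frame", "track_video",
    "ApexTracker",
]


@dataclass
class TrackerConfig:
    """Post-processing thresholds, all in full-frame pixel units.

    t_m : probability threshold for candidate pixels (0.75).
    r1 : search half-range; the crop is (2*r1+1) square.  200 suits GPU-class
         throughput, 50 is the CPU default.
    r2 : maximum distance of a candidate from the previous center (30).
    r3 : median-deviation gate, default 0.5 * r2.
    t1, t2 : benchmark bounds (seconds) for the adaptive search range.
    box_side : side of the box mask used for relearning pseudo-ground-truth
         and the optional first-frame user box.
    """

    t_m: float = 0.75
    r1: int = 50
    r2: float = 30.0
    r3: float | None = None
    t1: float = 0.04
    t2: float = 0.17
    box_side: int = 33

    def __post_init__(self) -> None:
        if self.r3 is None:
            self.r3 = 0.5 * self.r2
        if not 0 < self.t_m < 1:
            raise ValueError("t_m must be in (0, 1)")
        if self.r1 <= 0 or self.r2 <= 0 or self.r3 <= 0:
            raise ValueError("r1, r2 and r3 must be positive")
        if not self.t1 < self.t2:
            raise ValueError("t1 must be smaller than t2")
        if self.box_side < 1 or self.box_side % 2 == 0:
            raise ValueError("box_side must be odd and positive")


class CandidateSet:
    """Candidate apex pixels in full-frame coordinates."""

    def __init__(self, points) -> None:
        pts = np.asarray(points, dtype=np.float64)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (x, y)")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def median_x(self) -> float:
        return float(np.median(self.points[:, 0]))

    @property
    def median_y(self) -> float:
        return float(np.median(self.points[:, 1]))


@dataclass
class TrackerState:
    """Mutable tracking-loop state for one video."""

    params: list[np.ndarray]
    anchor: list[np.ndarray]
    prev_center: tuple[float, float] | None = None
    frame_index: int = 0
    relearn_events: list[tuple[int, int]] = field(default_factory=list)


@dataclass(frozen=True)
class FrameRecord:
    frame_index: int
    x: float
    y: float
    lost: bool
    relearned: bool
    suspicion: float
    relearn_iters: int


@dataclass
class TrackResult:
    """Per-frame tracking output for one video."""

    records: list[FrameRecord]
    name: str = ""
    config: TrackerConfig | None = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def centers(self) -> np.ndarray:
        """(n, 2) array of predicted (x, y); NaN where no center exists."""
        return np.array([[r.x, r.y] for r in self.records], dtype=np.float64)

    @property
    def lost(self) -> np.ndarray:
        return np.array([r.lost for r in self.records], dtype=bool)

    @property
    def n_lost(self) -> int:
        return int(self.lost.sum())

    @property
    def n_relearn_events(self) -> int:
        return sum(1 for r in self.records if r.relearned)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": [r.frame_index for r in self.records],
            "x": [r.x for r in self.records],
            "y": [r.y for r in self.records],
            "lost": [int(r.lost) for r in self.records],
            "relearned": [int(r.relearned) for r in self.records],
        })

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path) -> "TrackResult":
        df = pd.read_csv(path)
        recs = [FrameRecord(int(r.frame), float(r.x), float(r.y),
                            bool(r.lost), bool(r.relearned),
                            float("nan"), 0)
                for r in df.itertuples()]
        return cls(recs, name=Path(path).stem)


# ---------------------------------------------------------------------------
# pipeline stages

def crop_search_range(frame: np.ndarray, prev_center, r1: int):
    """Crop the (2*r1+1)-square search range centred on ``prev_center``.

    On the first frame (no previous center) the whole frame is returned.
    Near borders the window is shifted inward so its size never changes.
    Returns ``(crop, (offset_x, offset_y))``.
    """
    if r1 <= 0:
        raise ValueError("r1 must be positive")
    h, w = frame.shape[:2]
    if prev_center is None:
        return frame, (0, 0)
    size = 2 * r1 + 1
    if size > w or size > h:
        warnings.warn(
            f"search range {size}x{size} exceeds the {w}x{h} frame; "
            "falling back to the whole frame", stacklevel=2)
        return frame, (0, 0)
    cx, cy = prev_center
    ox = int(np.clip(int(round(cx)) - r1, 0, w - size))
    oy = int(np.clip(int(round(cy)) - r1, 0, h - size))
    return frame[oy:oy + size, ox:ox + size], (ox, oy)


def threshold_map(p: np.ndarray, t_m: float) -> np.ndarray:
    """Binary map: 1 where probability >= t_m (boundary inclusive)."""
    if not 0 < t_m < 1:
        raise ValueError("t_m must be in (0, 1)")
    return (np.asarray(p) >= t_m).astype(np.uint8)


def _median_gate(candidates: CandidateSet, r3: float) -> CandidateSet:
    if len(candidates) == 0:
        return candidates
    pts = candidates.points
    med = np.median(pts, axis=0)
    keep = (np.abs(pts[:, 0] - med[0]) <= r3) & (np.abs(pts[:, 1] - med[1]) <= r3)
    return CandidateSet(pts[keep])


def remove_outliers(candidates: CandidateSet, prev_center, r2: float,
                    r3: float) -> CandidateSet:
    """Two-stage outlier filter.

    1. Drop candidates further than ``r2`` (Euclidean) from the previous
       apex center.
    2. Drop candidates whose x or y deviates from the survivors' medians
       by more than ``r3``.

    May return an empty set; the caller treats that as a lost frame.
    """
    if len(candidates) == 0:
        return candidates
    pts = candidates.points
    d = np.hypot(pts[:, 0] - prev_center[0], pts[:, 1] - prev_center[1])
    survivors = CandidateSet(pts[d <= r2])
    if len(survivors) == 0:
        return survivors
    return _median_gate(survivors, r3)


def locate_center(candidates: CandidateSet):
    """Mean coordinates of the candidates, or None when the set is empty."""
    if len(candidates) == 0:
        return None
    m = candidates.points.mean(axis=0)
    return (float(m[0]), float(m[1]))


def select_search_range(bench_time_s: float, config: TrackerConfig) -> int:
    """Pick R1 from the measured inference time of a 401x401 probe:
    fast (< t1) -> 200, slow (> t2) -> 50, otherwise 100."""
    if bench_time_s <= 0:
        raise ValueError("bench_time_s must be positive")
    if bench_time_s < config.t1:
        return 200
    if bench_time_s > config.t2:
        return 50
    return 100


def benchmark_inference(params: list[np.ndarray], probe_size: int = 401,
                        repeats: int = 1) -> float:
    """Seconds per forward pass on a mid-grey probe image."""
    probe = np.full((probe_size, probe_size, 3), 127, dtype=np.uint8)
    infer(params, probe)  # warm-up
    t0 = time.perf_counter()
    for _ in range(repeats):
        infer(params, probe)
    return (time.perf_counter() - t0) / repeats


# ---------------------------------------------------------------------------
# tracking loop

def _detect(params, crop, offset, prev_center, config: TrackerConfig):
    prob = infer(params, crop)
    binary = threshold_map(prob, config.t_m)
    rows, cols = np.nonzero(binary)
    cand = CandidateSet(np.column_stack([cols + offset[0], rows + offset[1]])
                        .astype(np.float64))
    if prev_center is not None:
        cand = remove_outliers(cand, prev_center, config.r2, config.r3)
    else:
        cand = _median_gate(cand, config.r3)
    return prob, cand


def _pseudo_ground_truth(cand: CandidateSet, prev_center, crop_shape, offset,
                         box_side: int) -> np.ndarray:
    """Binary pseudo-ground-truth on the crop for suspicion / relearning.

    The post-processed segmentation itself when it is non-empty; otherwise
    (total detection failure) a box mask centred on the last tracked apex
    position — the most recent location the tracker trusted.
    """
    b = np.zeros(crop_shape, dtype=np.uint8)
    if len(cand):
        xs = (cand.points[:, 0] - offset[0]).astype(int)
        ys = (cand.points[:, 1] - offset[1]).astype(int)
        b[ys, xs] = 1
    elif prev_center is not None:
        cx = prev_center[0] - offset[0]
        cy = prev_center[1] - offset[1]
        h, w = crop_shape
        if 0 <= cx < w and 0 <= cy < h:
            b = make_mask((cx, cy), crop_shape, box_side)
    return b


def track_frame(state: TrackerState, frame: np.ndarray, config: TrackerConfig,
                relearn_config: RelearnConfig | None = None,
                relearn_enabled: bool = True) -> FrameRecord:
    """Process one frame, mutating ``state``; returns the frame's record."""
    crop, offset = crop_search_range(frame, state.prev_center, config.r1)
    prob, cand = _detect(state.params, crop, offset, state.prev_center, config)

    suspicion = float("nan")
    relearned = False
    iters = 0
    if relearn_enabled and relearn_config is not None:
        b_init = _pseudo_ground_truth(cand, state.prev_center, crop.shape[:2],
                                      offset, config.box_side)
        suspicion = compute_suspicion(prob, b_init)
        if suspicion > relearn_config.t_s and b_init.any():
            state.params, state.anchor, iters, _ = relearn_on_frame(
                state.params, state.anchor, crop, b_init, relearn_config)
            relearned = True
            state.relearn_events.append((state.frame_index, iters))
            prob, cand = _detect(state.params, crop, offset,
                                 state.prev_center, config)

    center = locate_center(cand)
    if center is None:
        lost = True
        x, y = state.prev_center if state.prev_center is not None \
            else (float("nan"), float("nan"))
    else:
        lost = False
        x, y = center
        state.prev_center = center
    record = FrameRecord(state.frame_index, x, y, lost, relearned,
                         suspicion, iters)
    state.frame_index += 1
    return record


def track_video(seq, pretrained_params: list[np.ndarray],
                config: TrackerConfig | None = None,
                relearn_config: RelearnConfig | None = None,
                relearn_enabled: bool = True,
                initial_box=None, name: str | None = None) -> TrackResult:
    """Track one video from its pretrained model.

    ``seq`` is a :class:`FrameSequence` or an (n, H, W, 3) array.  The
    model is reset to ``pretrained_params`` first (adaptation never leaks
    across videos).  ``initial_box`` — optional user box (x, y, w, h) on
    frame 0; the model is refined on frame 0 against a box mask built from
    its center before tracking starts.
    """
    config = config or TrackerConfig()
    relearn_config = relearn_config or RelearnConfig()
    frames = seq.frames if isinstance(seq, FrameSequence) else np.asarray(seq)
    if name is None:
        name = seq.name if isinstance(seq, FrameSequence) else ""
    params, anchor = reset(pretrained_params)
    state = TrackerState(params=params, anchor=anchor)

    if initial_box is not None:
        bx, by, bw, bh = initial_box
        center = (bx + (bw - 1) / 2.0, by + (bh - 1) / 2.0)
        b_init = make_mask(center, frames[0].shape[:2], config.box_side)
        state.params, state.anchor, iters, _ = relearn_on_frame(
            state.params, state.anchor, frames[0], b_init, relearn_config)
        if iters:
            state.relearn_events.append((0, iters))
        state.prev_center = center

    records = [track_frame(state, f, config, relearn_config, relearn_enabled)
               for f in frames]
    return TrackResult(records, name=name, config=config)


# ---------------------------------------------------------------------------
# estimator

class ApexTracker(BaseEstimator):
    """Full tracking pipeline as a scikit-learn style estimator.

    ``fit(X, y)`` pretrains the segmentation network on frames/masks;
    ``predict(seq)`` tracks a video and returns a :class:`TrackResult`.
    A pre-fitted :class:`UNetSegmenter` can be passed instead of training.

    Parameters mirror :class:`UNetSegmenter`, :class:`TrackerConfig` and
    :class:`RelearnConfig`; see those classes for semantics.
    """

    def __init__(self, base_channels: int = 16, learning_rate: float = 0.01,
                 batch_size: int = 8, epochs: int = 20,
                 target_loss: float | None = None, seed: int = 0,
                 t_m: float = 0.75, r1: int = 50, r2: float = 30.0,
                 r3: float | None = None, box_side: int = 33,
                 relearn: bool = True, t_s: float = 0.95, c: float = 0.6,
                 alpha: float = 0.5, eta: float = 0.01,
                 time_cap_s: float = 3.0, max_iters: int = 100,
                 segmenter: UNetSegmenter | None = None):
        self.base_channels = base_channels
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.target_loss = target_loss
        self.seed = seed
        self.t_m = t_m
        self.r1 = r1
        self.r2 = r2
        self.r3 = r3
        self.box_side = box_side
        self.relearn = relearn
        self.t_s = t_s
        self.c = c
        self.alpha = alpha
        self.eta = eta
        self.time_cap_s = time_cap_s
        self.max_iters = max_iters
        self.segmenter = segmenter

    def fit(self, X, y=None):
        if self.segmenter is not None:
            self.segmenter._check_fitted()
            self.segmenter_ = self.segmenter
        else:
            self.segmenter_ = UNetSegmenter(
                base_channels=self.base_channels,
                learning_rate=self.learning_rate, batch_size=self.batch_size,
                epochs=self.epochs, target_loss=self.target_loss,
                threshold=self.t_m, seed=self.seed).fit(X, y)
        self.tracker_config_ = TrackerConfig(
            t_m=self.t_m, r1=self.r1, r2=self.r2, r3=self.r3,
            box_side=self.box_side)
        self.relearn_config_ = RelearnConfig(
            t_s=self.t_s, c=self.c, alpha=self.alpha, eta=self.eta,
            time_cap_s=self.time_cap_s, max_iters=self.max_iters)
        return self

    def predict(self, seq, initial_box=None) -> TrackResult:
        if not hasattr(self, "segmenter_"):
            if self.segmenter is not None:
                self.fit(None)
            else:
                raise RuntimeError("ApexTracker is not fitted; call fit() "
                                   "or pass a fitted segmenter")
        return track_video(seq, self.segmenter_.params_,
                           config=self.tracker_config_,
                           relearn_config=self.relearn_config_,
                           relearn_enabled=self.relearn,
                           initial_box=initial_box)
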