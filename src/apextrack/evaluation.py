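"""Tracking metrics and baseline trackers.

Metrics follow the evaluation protocol for apex tracking: the per-frame
error is the Euclidean distance between predicted and annotated centers;
a frame counts as *successful* when a prediction exists, the frame was
not flagged lost, and the error is within ``success_radius_px`` (default
20 px — the largest apex displacement ever observed between consecutive
time-lapse frames, so a tracker outside it has effectively lost its
target).  TSR (Tracking Success Rate) is the percentage of successful
frames; error statistics are computed over the successful frames only and
converted to millimetres with the per-video scale when one is known.
Error spread uses the population standard deviation.

The Wilcoxon signed-rank comparison between two trackers pairs per-frame
errors up to the first fatal failure of either tracker.

The block-matching baseline is a plain sum-of-absolute-differences
template matcher: it needs an initial apex position and simply follows
the best-matching block from frame to frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset_io import ApexAnnotation, FrameSequence, px_to_mm
from .tracker import FrameRecord, TrackResult

__all__ = ["EvalReport", "euclidean_error", "per_frame_errors", "score",
           "wilcoxon_paired", "block_matching_baseline"]


@dataclass
class EvalReport:
    """Per-video tracking report (mm fields None without a scale)."""

    tsr: float
    error_mean_px: float | None
    error_std_px: float | None
    error_mean_mm: float | None
    error_std_mm: float | None
    n_success_frames: int
    n_frames: int
    n_lost: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def euclidean_error(truth, pred) -> float:
    """Euclidean distance between annotated and predicted centers (px)."""
    return float(np.hypot(truth[0] - pred[0], truth[1] - pred[1]))


def per_frame_errors(result: TrackResult,
                     annotations: list[ApexAnnotation]) -> np.ndarray:
    """Per-frame pixel errors; NaN where no prediction exists."""
    if len(result) != len(annotations):
        raise ValueError(
            f"result has {len(result)} frames but {len(annotations)} "
            "annotations were given")
    ann = {a.frame_index: a.center for a in annotations}
    errors = np.full(len(result), np.nan)
    for i, rec in enumerate(result.records):
        truth = ann.get(rec.frame_index)
        if truth is None:
            raise ValueError(f"no annotation for frame {rec.frame_index}")
        if np.isfinite(rec.x) and np.isfinite(rec.y):
            errors[i] = euclidean_error(truth, (rec.x, rec.y))
    return errors


def score(result: TrackResult, annotations: list[ApexAnnotation],
          success_radius_px: float = 20.0,
          scale_mm_per_px: float | None = None) -> EvalReport:
    """Score one tracked video against its ground-truth annotations."""
    errors = per_frame_errors(result, annotations)
    lost = result.lost
    success = (~lost) & np.isfinite(errors) & (errors <= success_radius_px)
    n_success = int(success.sum())
    tsr = 100.0 * n_success / len(result)
    if n_success:
        mean_px = float(errors[success].mean())
        std_px = float(errors[success].std())  # population std
        mean_mm = px_to_mm(mean_px, scale_mm_per_px) if scale_mm_per_px else None
        std_mm = px_to_mm(std_px, scale_mm_per_px) if scale_mm_per_px else None
    else:
        mean_px = std_px = mean_mm = std_mm = None
    return EvalReport(tsr=tsr, error_mean_px=mean_px, error_std_px=std_px,
                      error_mean_mm=mean_mm, error_std_mm=std_mm,
                      n_success_frames=n_success, n_frames=len(result),
                      n_lost=int(lost.sum()))


def wilcoxon_paired(errors_a, errors_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-frame errors.

    Zero differences are dropped, tied ranks averaged; the exact null
    distribution is used whenever SciPy can provide it at the sample size.
    """
    a = np.asarray(errors_a, dtype=np.float64)
    b = np.asarray(errors_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired error lists must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs for the signed-rank test")
    d = a - b
    if np.all(d == 0):
        raise ValueError("all paired differences are zero; the signed-rank "
                         "test is degenerate")
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def block_matching_baseline(seq, init_center, block_side: int = 33,
                            search_radius: int = 20) -> TrackResult:
    """Sum-of-absolute-differences block matcher.

    Follows the ``block_side`` square template around the previous center;
    per frame it picks the integer displacement within ``search_radius``
    (Chebyshev) that minimises the SAD against the previous frame's block.
    Ties prefer the smallest displacement magnitude, then row-major order.
    Cannot detect the apex on its own, so an initial center is required.
    """
    if block_side < 1 or block_side % 2 == 0:
        raise ValueError("block_side must be odd and positive")
    frames = seq.frames if isinstance(seq, FrameSequence) else np.asarray(seq)
    h, w = frames.shape[1:3]
    half = (block_side - 1) // 2

    def clamp_center(cx, cy):
        ccx = float(np.clip(cx, half, w - 1 - half))
        ccy = float(np.clip(cy, half, h - 1 - half))
        if (ccx, ccy) != (cx, cy):
            import warnings
            warnings.warn("block-matching template clamped at frame border",
                          stacklevel=3)
        return ccx, ccy

    cx, cy = clamp_center(*map(float, init_center))
    records = [FrameRecord(0, cx, cy, False, False, float("nan"), 0)]

    # displacement grid, ordered row-major; magnitude used for tie-breaks
    r = search_radius
    dyy, dxx = np.mgrid[-r:r + 1, -r:r + 1]
    disp = np.column_stack([dxx.ravel(), dyy.ravel()])
    mag2 = (disp ** 2).sum(axis=1)

    for t in range(1, len(frames)):
        ix, iy = int(round(cx)), int(round(cy))
        template = frames[t - 1][iy - half:iy + half + 1,
                                 ix - half:ix + half + 1].astype(np.int32)
        sad = np.empty(len(disp), dtype=np.int64)
        for j, (dx, dy) in enumerate(disp):
            nx, ny = ix + dx, iy + dy
            if not (half <= nx <= w - 1 - half and half <= ny <= h - 1 - half):
                sad[j] = np.iinfo(np.int64).max
                continue
            block = frames[t][ny - half:ny + half + 1,
                              nx - half:nx + half + 1].astype(np.int32)
            sad[j] = int(np.abs(block - template).sum())
        best = sad.min()
        tied = np.flatnonzero(sad == best)
        tied = tied[mag2[tied] == mag2[tied].min()]
        j = int(tied[0])           # row-major order among remaining ties
        cx, cy = clamp_center(cx + disp[j, 0], cy + disp[j, 1])
        records.append(FrameRecord(t, cx, cy, False, False, float("nan"), 0))
    name = seq.name if isinstance(seq, FrameSequence) else ""
    return TrackResult(records, name=f"{name}_bm")
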