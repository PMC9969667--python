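"""Optional optical-flow baseline (KLT-style feature displacement).

Not part of the tested surface: a thin adapter over scikit-image's
iterative Lucas-Kanade optical flow for comparison workflows.  Like any
pure flow tracker it needs an initial apex position and cannot re-detect
a lost target.
"""

from __future__ import annotations

import numpy as np

from .dataset_io import FrameSequence
from .tracker import FrameRecord, TrackResult

__all__ = ["optical_flow_baseline"]


def optical_flow_baseline(seq, init_center, window_radius: int = 16,
                          **flow_kwargs) -> TrackResult:
    """Track by averaging iterative-LK optical flow in a window around the
    previous centre.  Requires scikit-image."""
    try:
        from skimage.color import rgb2gray
        from skimage.registration import optical_flow_ilk
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "the optical-flow baseline needs scikit-image") from exc

    frames = seq.frames if isinstance(seq, FrameSequence) else np.asarray(seq)
    h, w = frames.shape[1:3]
    cx, cy = map(float, init_center)
    records = [FrameRecord(0, cx, cy, False, False, float("nan"), 0)]
    prev_grey = rgb2gray(frames[0])
    for t in range(1, len(frames)):
        grey = rgb2gray(frames[t])
        v, u = optical_flow_ilk(prev_grey, grey, **flow_kwargs)
        x0 = int(np.clip(round(cx) - window_radius, 0, w - 1))
        x1 = int(np.clip(round(cx) + window_radius + 1, 1, w))
        y0 = int(np.clip(round(cy) - window_radius, 0, h - 1))
        y1 = int(np.clip(round(cy) + window_radius + 1, 1, h))
        cx = float(np.clip(cx + u[y0:y1, x0:x1].mean(), 0, w - 1))
        cy = float(np.clip(cy + v[y0:y1, x0:x1].mean(), 0, h - 1))
        records.append(FrameRecord(t, cx, cy, False, False, float("nan"), 0))
        prev_grey = grey
    name = seq.name if isinstance(seq, FrameSequence) else ""
    return TrackResult(records, name=f"{name}_klt")
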