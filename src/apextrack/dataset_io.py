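"""Frames, annotations, ground-truth masks, manifests, unit conversion.

Coordinate convention (used everywhere in this package): 0-based pixel
coordinates with the origin at the top-left corner, x growing rightward
and y growing downward.  Annotated apex coordinates are the *center* of
the annotation box; the ground-truth mask for a frame is a box_side x
box_side square of ones centred there (clipped at frame borders, never
shifted).

Annotation files are CSV with header ``frame,x,y``; manifests are YAML
lists with keys ``video``, ``annotations``, ``split`` and
``scale_mm_per_px``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

#: the native resolution the published tracker expects, as (width, height)
NATIVE_SIZE = (640, 480)

_FRAME_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


@dataclass
class FrameSequence:
    """Ordered RGB frames plus capture metadata.

    frames: (n, H, W, 3) uint8 array.
    frame_interval_minutes: capture cadence (time-lapse default: one frame
        every 2 minutes).
    scale_mm_per_px: physical scale, if known, for mm error reporting.
    """

    frames: np.ndarray
    frame_interval_minutes: float = 2.0
    scale_mm_per_px: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must be a (n, H, W, 3) array")
        if len(self.frames) < 1:
            raise ValueError("a FrameSequence needs at least one frame")
        if self.frame_interval_minutes <= 0:
            raise ValueError("frame_interval_minutes must be positive")
        if self.scale_mm_per_px is not None and self.scale_mm_per_px <= 0:
            raise ValueError("scale_mm_per_px must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(height, width) of every frame."""
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def timestamps_minutes(self) -> np.ndarray:
        return np.arange(len(self)) * self.frame_interval_minutes


@dataclass(frozen=True)
class ApexAnnotation:
    """Ground-truth apex center for one frame."""

    frame_index: int
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x, self.y)


def _natural_key(name: str):
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", name)]


def _resize_rgb(frame: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    from PIL import Image

    w, h = size
    return np.asarray(Image.fromarray(frame).resize((w, h), Image.BILINEAR))


def load_sequence(path, target_size: tuple[int, int] | None = NATIVE_SIZE,
                  frame_interval_minutes: float = 2.0,
                  scale_mm_per_px: float | None = None) -> FrameSequence:
    """Load a video file or a directory of numbered image frames.

    ``target_size`` (width, height): frames of a different size are
    resized with a warning, since the tracker's defaults are calibrated
    at 640x480.  Pass ``None`` to keep the native size (e.g. for the
    reduced-resolution synthetic videos).
    """
    p = Path(path)
    if not p.exists():
        raise IOError(f"no such video or frame directory: {p}")
    if p.is_dir():
        files = sorted(
            (f for f in p.iterdir() if f.suffix.lower() in _FRAME_EXTENSIONS),
            key=lambda f: _natural_key(f.name))
        if not files:
            raise IOError(f"frame directory is empty: {p}")
        frames = [_ensure_rgb(iio.imread(f)) for f in files]
    else:
        try:
            frames = [_ensure_rgb(fr) for fr in iio.imiter(p)]
        except Exception as exc:  # pragma: no cover - backend dependent
            raise IOError(f"could not read video file {p}: {exc}") from exc
        if not frames:
            raise IOError(f"video file contains no frames: {p}")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise IOError(f"frames in {p} have inconsistent dimensions: {shapes}")
    if target_size is not None:
        h, w = frames[0].shape[:2]
        if (w, h) != tuple(target_size):
            warnings.warn(
                f"resizing {w}x{h} frames from {p.name} to "
                f"{target_size[0]}x{target_size[1]}; the tracker's defaults "
                "are calibrated at that resolution", stacklevel=2)
            frames = [_resize_rgb(f, tuple(target_size)) for f in frames]
    return FrameSequence(np.stack(frames),
                         frame_interval_minutes=frame_interval_minutes,
                         scale_mm_per_px=scale_mm_per_px, name=p.stem)


def _ensure_rgb(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 2:
        frame = np.repeat(frame[..., None], 3, axis=-1)
    if frame.shape[-1] == 4:
        frame = frame[..., :3]
    return frame.astype(np.uint8)


def save_sequence(seq: FrameSequence, directory) -> None:
    """Write frames as zero-padded PNGs (``frame_0000.png``, ...)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        iio.imwrite(d / f"frame_{i:04d}.png", frame)


def read_annotations(path, frame_shape: tuple[int, int] | None = None
                     ) -> list[ApexAnnotation]:
    """Parse a ``frame,x,y`` CSV; rows sorted by frame, duplicates rejected.

    ``frame_shape`` (height, width), when given, bounds-checks each center.
    """
    p = Path(path)
    if not p.exists():
        raise IOError(f"no such annotation file: {p}")
    try:
        df = pd.read_csv(p)
    except Exception as exc:
        raise ValueError(f"could not parse {p}: {exc}") from exc
    required = ["frame", "x", "y"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{p}: expected header 'frame,x,y', got {list(df.columns)}")
    for col in required:
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if df[col].isna().any():
            line = int(df[df[col].isna()].index[0]) + 2  # +1 header, +1 1-based
            raise ValueError(f"{p}: malformed value in column '{col}' at line {line}")
    if df["frame"].duplicated().any():
        dup = int(df.loc[df["frame"].duplicated(), "frame"].iloc[0])
        raise ValueError(f"{p}: duplicate annotation for frame {dup}")
    df = df.sort_values("frame")
    anns = [ApexAnnotation(int(r.frame), float(r.x), float(r.y))
            for r in df.itertuples()]
    if frame_shape is not None:
        h, w = frame_shape
        for a in anns:
            if not (0 <= a.x < w and 0 <= a.y < h):
                raise ValueError(
                    f"{p}: annotation for frame {a.frame_index} at "
                    f"({a.x}, {a.y}) lies outside a {w}x{h} frame")
    return anns


def write_annotations(annotations: list[ApexAnnotation], path) -> None:
    df = pd.DataFrame({
        "frame": [a.frame_index for a in annotations],
        "x": [a.x for a in annotations],
        "y": [a.y for a in annotations],
    })
    df.to_csv(path, index=False)


def make_mask(annotation, frame_shape: tuple[int, int],
              box_side: int = 33) -> np.ndarray:
    """Binary ground-truth mask: a box_side x box_side square of ones
    centred on the annotated apex, clipped to the frame.

    ``annotation`` may be an :class:`ApexAnnotation` or an (x, y) pair.
    """
    if box_side < 1 or box_side % 2 == 0:
        raise ValueError(f"box_side must be an odd positive integer, got {box_side}")
    if isinstance(annotation, ApexAnnotation):
        cx, cy = annotation.center
    else:
        cx, cy = annotation
    h, w = frame_shape
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"center ({cx}, {cy}) outside {w}x{h} frame")
    half = (box_side - 1) // 2
    cx_i, cy_i = int(round(cx)), int(round(cy))
    mask = np.zeros((h, w), dtype=np.uint8)
    mask[max(0, cy_i - half):min(h, cy_i + half + 1),
         max(0, cx_i - half):min(w, cx_i + half + 1)] = 1
    return mask


def px_to_mm(distance_px: float, scale_mm_per_px: float | None) -> float:
    """Convert a pixel distance to millimetres using the per-video scale."""
    if scale_mm_per_px is None:
        raise ValueError(
            "no mm/pixel scale available for this video; supply one "
            "(e.g. from the dataset's per-video scale table)")
    if scale_mm_per_px <= 0:
        raise ValueError("scale_mm_per_px must be positive")
    if distance_px < 0:
        raise ValueError("distance_px must be non-negative")
    return distance_px * scale_mm_per_px


@dataclass
class ManifestEntry:
    video: Path
    annotations: Path | None
    split: str
    scale_mm_per_px: float | None = None

    def __post_init__(self) -> None:
        if self.split not in {"train", "val", "test"}:
            raise ValueError(f"split must be train/val/test, got {self.split!r}")


@dataclass
class DatasetManifest:
    entries: list[ManifestEntry] = field(default_factory=list)

    def split(self, tag: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.split == tag]


def load_manifest(path) -> DatasetManifest:
    """YAML manifest -> :class:`DatasetManifest`; referenced paths must exist.

    Relative paths are resolved against the manifest's directory.
    """
    p = Path(path)
    with open(p) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise ValueError(f"{p}: manifest must be a non-empty YAML list")
    entries = []
    for item in raw:
        video = (p.parent / item["video"]).resolve()
        ann = item.get("annotations")
        ann = (p.parent / ann).resolve() if ann else None
        if not video.exists():
            raise IOError(f"{p}: video path not readable: {video}")
        if ann is not None and not ann.exists():
            raise IOError(f"{p}: annotation path not readable: {ann}")
        entries.append(ManifestEntry(
            video=video, annotations=ann, split=item.get("split", "train"),
            scale_mm_per_px=item.get("scale_mm_per_px")))
    return DatasetManifest(entries)
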