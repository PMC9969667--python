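"""Seeded synthetic circumnutation videos with exact ground truth.

A bright, radially soft disk (the "apex") follows a near-elliptical path
with a slow upward growth drift over a dark solid background — the
kinematics of a circumnutating flowering stem as seen by a fixed
time-lapse camera.  Optional static distractor rectangles emulate rulers
and labels in the scene, an optional mid-video appearance change emulates
the apex changing morphology as it grows, and additive Gaussian pixel
noise emulates sensor noise.

The blob center at frame t is

    x(t) = cx + a * cos(omega * t + phase)
    y(t) = cy - growth * t + b * sin(omega * t + phase)

and the per-frame annotation is that point rounded to integer pixels.
Rendering is deterministic: every frame draws its noise from a stream
derived from (seed, frame index), so re-rendering a suffix of the video
(appearance perturbation) leaves earlier frames byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml

from .dataset_io import ApexAnnotation, FrameSequence, make_mask

__all__ = ["AppearanceShift", "SceneSpec", "SyntheticVideo",
           "generate_video", "generate_training_set", "perturb_appearance"]

#: the largest per-frame apex displacement the tracker assumes (pixels)
MAX_FRAME_DISPLACEMENT = 20.0


@dataclass(frozen=True)
class AppearanceShift:
    """Mid-video appearance change applied from ``frame_index`` onward."""

    frame_index: int
    color: tuple[int, int, int]
    radius: float | None = None


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic video (all lengths in pixels)."""

    frame_size: tuple[int, int] = (640, 480)      # (width, height)
    n_frames: int = 100
    background_color: tuple[int, int, int] = (14, 12, 16)
    blob_radius: float = 16.0
    blob_color: tuple[int, int, int] = (235, 235, 228)
    blob_softness: float = 3.0
    center: tuple[float, float] = (320.0, 300.0)
    semi_axes: tuple[float, float] = (60.0, 35.0)
    omega: float = 0.08          # rad / frame
    phase: float = 0.0
    growth: float = 0.35         # upward drift, px / frame
    appearance_shift: AppearanceShift | None = None
    distractors: tuple = ()      # (x, y, w, h, (r, g, b)) static rectangles
    noise_sigma: float = 5.0
    seed: int = 0
    box_side: int = 33           # ground-truth mask side for training pairs

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.blob_radius <= 0 or self.blob_softness <= 0:
            raise ValueError("blob_radius and blob_softness must be positive")
        self.validate_path()

    # -- kinematics ---------------------------------------------------------

    def path(self) -> np.ndarray:
        """(n_frames, 2) exact blob centers."""
        t = np.arange(self.n_frames, dtype=np.float64)
        a, b = self.semi_axes
        cx, cy = self.center
        x = cx + a * np.cos(self.omega * t + self.phase)
        y = cy - self.growth * t + b * np.sin(self.omega * t + self.phase)
        return np.column_stack([x, y])

    def max_radius(self) -> float:
        r = self.blob_radius
        if self.appearance_shift is not None and self.appearance_shift.radius:
            r = max(r, self.appearance_shift.radius)
        return r

    def validate_path(self) -> None:
        w, h = self.frame_size
        path = self.path()
        margin = self.max_radius()
        if (path[:, 0] < margin).any() or (path[:, 0] > w - 1 - margin).any() \
                or (path[:, 1] < margin).any() or (path[:, 1] > h - 1 - margin).any():
            raise ValueError("blob path leaves the frame (must stay at least "
                             "one blob radius from every border)")
        if self.n_frames > 1:
            disp = np.hypot(*np.diff(path, axis=0).T)
            if disp.max() > MAX_FRAME_DISPLACEMENT:
                raise ValueError(
                    f"per-frame displacement {disp.max():.1f} px exceeds the "
                    f"{MAX_FRAME_DISPLACEMENT:.0f} px motion bound")
        clearance = margin + self.blob_softness + 2.0
        for (dx, dy, dw, dh, _color) in self.distractors:
            near = ((path[:, 0] > dx - clearance)
                    & (path[:, 0] < dx + dw + clearance)
                    & (path[:, 1] > dy - clearance)
                    & (path[:, 1] < dy + dh + clearance))
            if near.any():
                raise ValueError("a distractor overlaps the blob path envelope")

    # -- presets ------------------------------------------------------------

    @classmethod
    def reduced(cls, seed: int = 0, **overrides) -> "SceneSpec":
        """Reduced-resolution preset (48x48 frames, box_side 5).

        Geometry is scaled down proportionally from the full-size scene
        so CPU training and test runs stay fast; pass overrides to vary
        individual fields (e.g. a larger ``frame_size`` canvas with the
        same blob appearance).
        """
        defaults = dict(
            frame_size=(48, 48), n_frames=200,
            blob_radius=3.0, blob_softness=1.2,
            center=(24.0, 29.0), semi_axes=(6.0, 4.0),
            omega=0.12, phase=0.0, growth=0.028,
            noise_sigma=5.0, box_side=5, seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)

    # -- (de)serialisation --------------------------------------------------

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SceneSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("appearance_shift"):
            s = d["appearance_shift"]
            d["appearance_shift"] = AppearanceShift(
                int(s["frame_index"]), tuple(s["color"]),
                s.get("radius"))
        for key in ("frame_size", "background_color", "blob_color", "center",
                    "semi_axes"):
            if key in d:
                d[key] = tuple(d[key])
        if "distractors" in d:
            d["distractors"] = tuple(
                (r[0], r[1], r[2], r[3], tuple(r[4])) for r in d["distractors"])
        return cls(**d)


@dataclass
class SyntheticVideo:
    sequence: FrameSequence
    annotations: list[ApexAnnotation]
    spec: SceneSpec

    def __post_init__(self) -> None:
        if len(self.annotations) != len(self.sequence):
            raise ValueError("one annotation per frame is required")

    def training_pairs(self) -> list[tuple[np.ndarray, np.ndarray]]:
        h, w = self.sequence.frame_shape
        return [(f, make_mask(a, (h, w), self.spec.box_side))
                for f, a in zip(self.sequence.frames, self.annotations)]


def _render_frame(spec: SceneSpec, t: int, center: np.ndarray) -> np.ndarray:
    w, h = spec.frame_size
    canvas = np.empty((h, w, 3), dtype=np.float64)
    canvas[:] = spec.background_color
    for (dx, dy, dw, dh, color) in spec.distractors:
        canvas[max(0, dy):dy + dh, max(0, dx):dx + dw] = color

    color = np.array(spec.blob_color, dtype=np.float64)
    radius = spec.blob_radius
    shift = spec.appearance_shift
    if shift is not None and t >= shift.frame_index:
        color = np.array(shift.color, dtype=np.float64)
        if shift.radius is not None:
            radius = shift.radius

    # draw the anti-aliased soft disk inside its bounding window only
    cx, cy = center
    ext = int(np.ceil(radius + spec.blob_softness)) + 1
    x0, x1 = max(0, int(cx) - ext), min(w, int(cx) + ext + 1)
    y0, y1 = max(0, int(cy) - ext), min(h, int(cy) + ext + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - cx, yy - cy)
    alpha = np.clip((radius + spec.blob_softness - d) / spec.blob_softness, 0.0, 1.0)
    patch = canvas[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1] = patch * (1.0 - alpha[..., None]) + color * alpha[..., None]

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, t]))
        canvas += rng.normal(0.0, spec.noise_sigma, size=canvas.shape)
    return np.clip(np.round(canvas), 0, 255).astype(np.uint8)


def generate_video(spec: SceneSpec) -> SyntheticVideo:
    """Render the scene; deterministic under ``spec.seed``."""
    spec.validate_path()
    path = spec.path()
    frames = np.stack([_render_frame(spec, t, path[t])
                       for t in range(spec.n_frames)])
    annotations = [ApexAnnotation(t, float(np.round(path[t, 0])),
                                  float(np.round(path[t, 1])))
                   for t in range(spec.n_frames)]
    seq = FrameSequence(frames, scale_mm_per_px=None,
                        name=f"synthetic_seed{spec.seed}")
    return SyntheticVideo(seq, annotations, spec)


def generate_training_set(specs) -> list[tuple[np.ndarray, np.ndarray]]:
    """(frame, ground-truth mask) pairs for every frame of every spec."""
    specs = list(specs)
    if not specs:
        raise ValueError("need at least one scene spec")
    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    for spec in specs:
        pairs.extend(generate_video(spec).training_pairs())
    return pairs


def perturb_appearance(video: SyntheticVideo,
                       shift: AppearanceShift) -> SyntheticVideo:
    """Re-render frames at/after ``shift.frame_index`` with the new look.

    Annotations (the motion) are unchanged; frames before the shift are
    byte-identical to the input video's.
    """
    if not 0 <= shift.frame_index < video.spec.n_frames:
        raise ValueError("shift frame index outside the video")
    new_spec = dataclasses.replace(video.spec, appearance_shift=shift)
    return generate_video(new_spec)
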