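"""Desk-scale study conditions: reduced-resolution scenes, training, scoring.

The real apex dataset is an external download, so the package's
end-to-end claims are exercised on a scaled-down analog: 48x48 synthetic
circumnutation videos (geometry scaled down proportionally from the
full-size scene), a slim U-Net (base width 4), and the tracker with its
thresholds scaled the same way.  Everything here is deterministic given
one integer seed; the same functions back the test suite and the
acceptance script.
"""

from __future__ import annotations

import numpy as np

from .evaluation import score
from .relearn import RelearnConfig
from .segmentation_model import UNetSegmenter
from .synthetic_data import SceneSpec, generate_training_set, generate_video
from .tracker import TrackerConfig, track_video

__all__ = ["reduced_tracker_config", "sample_reduced_specs",
           "train_reduced_segmenter", "headline_tracking_benchmark"]

#: side of the reduced frames; full-scale geometry shrinks proportionally
REDUCED_FRAME_SIDE = 48


def reduced_tracker_config(**overrides) -> TrackerConfig:
    """Tracker thresholds scaled to the 48x48 reduced scenes.

    R1/R2/R3/box_side shrink with the frame (R1 50 -> 8 etc.); the
    probability threshold T_m is resolution-free and stays at 0.75.
    """
    defaults = dict(t_m=0.75, r1=8, r2=5.0, box_side=5)
    defaults.update(overrides)
    return TrackerConfig(**defaults)


def _child_seed(seed: int, *tags: int) -> int:
    """Derive an independent 31-bit child seed."""
    return int(np.random.SeedSequence([seed, *tags]).generate_state(1)[0]
               & 0x7FFFFFFF)


def sample_reduced_specs(seed: int, n_videos: int, n_frames: int = 200,
                         group: int = 0) -> list[SceneSpec]:
    """Draw ``n_videos`` reduced scene specs with varied kinematics/looks.

    ``group`` separates draws (e.g. training vs evaluation videos) so the
    two sets differ even under the same base seed.
    """
    specs = []
    for i in range(n_videos):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, group, i]))
        # ruler/label-like static rectangles hugging the frame edges, away
        # from the path envelope; their mid-grey tones force the segmenter
        # to learn the apex's appearance rather than "any bright pixel"
        grey = lambda: tuple(int(v) for v in rng.integers(95, 165, 3))  # noqa: E731
        distractors = ((0, int(rng.integers(6, 20)), 3, 30, grey()),
                       (45, int(rng.integers(22, 34)), 3, 12, grey()),
                       (int(rng.integers(8, 30)), 0, 12, 4, grey()))
        specs.append(SceneSpec.reduced(
            seed=_child_seed(seed, group, i, 999),
            n_frames=n_frames,
            center=(rng.uniform(21, 27), rng.uniform(28, 31)),
            semi_axes=(rng.uniform(5, 7), rng.uniform(3, 4.5)),
            omega=rng.uniform(0.08, 0.15),
            phase=rng.uniform(0, 2 * np.pi),
            growth=rng.uniform(0.02, 0.035),
            blob_radius=rng.uniform(2.7, 3.3),
            blob_color=tuple(int(v) for v in rng.integers(215, 246, 3)),
            background_color=tuple(int(v) for v in rng.integers(8, 36, 3)),
            distractors=distractors,
        ))
    return specs


def train_reduced_segmenter(train_specs, seed: int, base_channels: int = 4,
                            epochs: int = 20,
                            target_loss: float | None = 0.05) -> UNetSegmenter:
    """Pretrain the slim segmenter on every frame of the given scenes.

    SGD with the standard settings (lr 0.01, batch 8), for up to
    ``epochs`` epochs with an early stop once the epoch-mean Soft Dice
    loss falls below ``target_loss`` (0.05 ~ IoU above 0.95, i.e. the
    box mask is essentially recovered).
    """
    pairs = generate_training_set(train_specs)
    frames = np.stack([f for f, _ in pairs])
    masks = np.stack([m for _, m in pairs])
    seg = UNetSegmenter(base_channels=base_channels, learning_rate=0.01,
                        batch_size=8, epochs=epochs, target_loss=target_loss,
                        seed=_child_seed(seed, 7))
    return seg.fit(frames, masks)


def headline_tracking_benchmark(seed: int, n_train: int = 3, n_eval: int = 2,
                                n_frames: int = 200, epochs: int = 20,
                                base_channels: int = 4,
                                success_radius_px: float = 20.0,
                                relearn: bool = True) -> dict:
    """Train-then-track benchmark on seeded synthetic circumnutation videos.

    Generates ``n_train`` training and ``n_eval`` evaluation videos,
    pretrains the reduced segmenter, runs the full tracker (search-range
    cropping, outlier removal, Model Update) on the evaluation videos and
    scores them at the default success radius.

    Returns a dict with the pooled ``tsr`` (percent), the number of
    evaluated frames ``n``, per-video reports, and the training loss
    history.
    """
    train_specs = sample_reduced_specs(seed, n_train, n_frames, group=0)
    eval_specs = sample_reduced_specs(seed, n_eval, n_frames, group=1)
    seg = train_reduced_segmenter(train_specs, seed, base_channels, epochs)

    config = reduced_tracker_config()
    relearn_config = RelearnConfig()
    reports = []
    n_success = 0
    n_total = 0
    for spec in eval_specs:
        video = generate_video(spec)
        result = track_video(video.sequence, seg.params_, config=config,
                             relearn_config=relearn_config,
                             relearn_enabled=relearn)
        report = score(result, video.annotations,
                       success_radius_px=success_radius_px)
        reports.append(report)
        n_success += report.n_success_frames
        n_total += report.n_frames
    return {
        "tsr": 100.0 * n_success / n_total,
        "n": n_total,
        "per_video": [r.as_dict() for r in reports],
        "loss_history": seg.loss_history_,
        "epochs_run": len(seg.loss_history_),
    }
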