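"""Online Model Update: suspicion scoring and anchored relearning.

When the tracker suspects the current segmentation is grossly wrong it
refines the network on the current frame alone, using the frame's own
post-processed binary segmentation as pseudo-ground-truth.  To keep the
pretrained competence, each refinement step blends a plain SGD step with
an anchor parameter set W_T:

    W_{k+1} = (1 - alpha) * W_T + alpha * (W_k - eta_k * grad L(W_k))

The *suspicion* score is the same Laplace-smoothed Soft Dice loss used in
training, evaluated between the probability map and the binary map.  The
refinement loop runs until suspicion < c * T_s, a wall-clock cap, or an
iteration cap; the refined parameters then become the new anchor for the
rest of the video.  The anchor and the live parameters are both reset to
the pretrained checkpoint whenever a new video starts.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .segmentation_model import infer_with_grad, soft_dice_loss

__all__ = ["RelearnConfig", "compute_suspicion", "blended_update",
           "relearn_on_frame", "reset"]


@dataclass
class RelearnConfig:
    """Model Update settings.

    t_s : suspicion threshold that triggers relearning (0.95).
    c : stop factor; the loop exits once suspicion < c * t_s (0.6).
    alpha : blend weight between the anchor and the SGD step, in (0, 1).
        The steady-state displacement of the iteration from the anchor
        scales with alpha / (1 - alpha) * eta, so alpha near 1 with a
        moderate eta lets an episode genuinely adapt while still being
        pulled back toward the pretrained behaviour.
    eta : relearning step size.
    time_cap_s : wall-clock cap on one relearning episode (3 s).
    max_iters : iteration cap, so behaviour is hardware-independent.
    """

    t_s: float = 0.95
    c: float = 0.6
    alpha: float = 0.9
    eta: float = 0.05
    time_cap_s: float = 3.0
    max_iters: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.c < 1:
            raise ValueError("c must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.t_s <= 1:
            raise ValueError("t_s must be in (0, 1]")
        if self.eta < 0 or self.time_cap_s < 0 or self.max_iters < 0:
            raise ValueError("eta, time_cap_s and max_iters must be >= 0")


def compute_suspicion(p: np.ndarray, b_init: np.ndarray) -> float:
    """Soft Dice loss between the probability map and the frame's binary
    segmentation; high values mean the two disagree badly."""
    return soft_dice_loss(p, b_init)


def blended_update(w_k: list[np.ndarray], w_t: list[np.ndarray],
                   grad: list[np.ndarray], eta: float, alpha: float
                   ) -> list[np.ndarray]:
    """One anchored update: (1 - alpha) * W_T + alpha * (W_k - eta * grad)."""
    if len(w_k) != len(w_t) or len(w_k) != len(grad):
        raise ValueError("parameter structures do not match")
    out = []
    for pk, pt, g in zip(w_k, w_t, grad):
        if pk.shape != pt.shape or pk.shape != np.shape(g):
            raise ValueError("parameter structures do not match")
        out.append(((1.0 - alpha) * pt + alpha * (pk - eta * np.asarray(g)))
                   .astype(pk.dtype))
    return out


def relearn_on_frame(params: list[np.ndarray], w_t: list[np.ndarray],
                     crop: np.ndarray, b_init: np.ndarray,
                     config: RelearnConfig):
    """Refine the model on one (cropped) frame with ``b_init`` as ground truth.

    Returns ``(params, w_t, iterations, final_suspicion)``.  The anchor
    ``w_t`` is held fixed during the loop and replaced by the refined
    parameters afterwards (they seed the next relearning in this video).
    """
    t0 = time.monotonic()
    iters = 0
    suspicion = None
    stop = config.c * config.t_s
    while True:
        prob, suspicion, grads = infer_with_grad(params, crop, b_init)
        if suspicion < stop:
            break
        if iters >= config.max_iters or time.monotonic() - t0 >= config.time_cap_s:
            break
        params = blended_update(params, w_t, grads, config.eta, config.alpha)
        iters += 1
    if iters > 0:
        w_t = [p.copy() for p in params]
    return params, w_t, iters, float(suspicion)


def reset(pretrained: list[np.ndarray]):
    """Restore live parameters and the anchor from the pretrained snapshot."""
    return [p.copy() for p in pretrained], [p.copy() for p in pretrained]
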