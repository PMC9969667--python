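"""Apex segmentation: Laplace-smoothed Soft Dice loss, SGD training, inference.

The segmenter is a slim four-level U-Net (see :mod:`apextrack.unet`) that
maps an RGB frame (or a cropped search range) to a per-pixel probability
that the pixel belongs to the flowering apex.  Training minimises

    L(P, B) = 1 - (sum_i p_i b_i + 1) / (sum_i p_i + sum_i b_i - sum_i p_i b_i + 1)

i.e. one minus a smoothed intersection-over-union between the probability
map ``P`` and the binary ground-truth box mask ``B``; the +1 terms
(Laplace smoothing) keep the loss and its gradient finite when both maps
are empty.

:class:`UNetSegmenter` packages the pieces as a scikit-learn style
estimator; the module-level functions (:func:`build_network`,
:func:`soft_dice_loss`, :func:`train`, :func:`infer`) are the equivalent
functional surface used by the tracker.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from . import unet
from ._nn import FLOAT
from .unet import DIVISOR, NetworkConfig

__all__ = [
    "NetworkConfig", "TrainConfig", "build_network", "soft_dice_loss",
    "train", "infer", "UNetSegmenter", "save_checkpoint", "load_checkpoint",
]


#: fixed affine input normalisation gain (see _as_net_input)
INPUT_SCALE = 6.0


# ---------------------------------------------------------------------------
# loss

def _validate_pair(p: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if p.shape != b.shape:
        raise ValueError(f"shape mismatch: P {p.shape} vs B {b.shape}")
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("probability map values must lie in [0, 1]")
    if not np.isin(b, (0.0, 1.0)).all():
        raise ValueError("ground-truth mask must be binary")
    return p, b


def soft_dice_loss(p: np.ndarray, b: np.ndarray) -> float:
    """Laplace-smoothed Soft Dice (IoU-form) loss; 0 iff P == B, always < 1."""
    p, b = _validate_pair(p, b)
    inter = float((p * b).sum())
    union = float(p.sum() + b.sum() - inter)
    return 1.0 - (inter + 1.0) / (union + 1.0)


def _soft_dice_grad(p: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss and dL/dp, without re-validating (hot path)."""
    pb = p * b
    inter = float(pb.sum())
    union = float(p.sum() + b.sum() - inter)
    denom = union + 1.0
    loss = 1.0 - (inter + 1.0) / denom
    # d inter/dp = b ; d union/dp = 1 - b
    grad = -(b * denom - (inter + 1.0) * (1.0 - b)) / (denom * denom)
    return loss, grad.astype(FLOAT)


# ---------------------------------------------------------------------------
# config / parameter construction

@dataclass
class TrainConfig:
    """Minibatch SGD settings (plain SGD, constant learning rate)."""

    optimizer: str = "sgd"
    learning_rate: float = 0.01
    batch_size: int = 8
    epochs: int = 20
    seed: int = 0
    #: optional early stop: finish once an epoch-mean loss falls below this
    target_loss: float | None = None

    def __post_init__(self) -> None:
        if self.optimizer != "sgd":
            raise ValueError("only plain SGD is supported")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


def build_network(config: NetworkConfig, seed: int) -> list[np.ndarray]:
    """Deterministically initialised parameter list for the U-Net."""
    return unet.init_params(config, seed)


def _as_net_input(images: np.ndarray) -> np.ndarray:
    """(N, H, W, 3) uint8 [0, 255] or float [0, 1] -> (N, 3, H, W) float32.

    Inputs are centred at mid-grey and amplified by ``INPUT_SCALE``.  A
    fixed affine normalisation keeps full frames and search-range crops
    on the same scale, and the gain puts the (1/union-scaled) Soft Dice
    gradients at a magnitude where the standard SGD step size makes
    steady progress.
    """
    x = np.asarray(images)
    if x.ndim == 3:
        x = x[None]
    if x.dtype == np.uint8:
        x = x.astype(FLOAT) / 255.0
    else:
        x = x.astype(FLOAT)
    x = (x - 0.5) * INPUT_SCALE
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


# ---------------------------------------------------------------------------
# training

def train(params: list[np.ndarray], dataset, config: TrainConfig):
    """Minibatch SGD on the Soft Dice loss.

    ``dataset``: sequence of (frame, mask) pairs; frames are (H, W, 3)
    uint8, masks (H, W) binary.  Returns ``(params, loss_history)`` where
    ``loss_history`` is the per-epoch mean of the per-frame losses.
    Fully reproducible: shuffling is driven by ``config.seed`` only.
    """
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    frames = _as_net_input(np.stack([f for f, _ in dataset]))
    masks = np.stack([np.asarray(m, dtype=FLOAT) for _, m in dataset])[:, None]
    n = frames.shape[0]
    params = [p.copy() for p in params]
    rng = np.random.default_rng(config.seed)
    history: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses: list[float] = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, bb = frames[idx], masks[idx]
            prob, info = unet.forward(params, xb)
            dprob = np.empty_like(prob)
            for j in range(xb.shape[0]):
                loss_j, grad_j = _soft_dice_grad(
                    prob[j].astype(np.float64), bb[j].astype(np.float64))
                losses.append(loss_j)
                dprob[j] = grad_j / xb.shape[0]
            grads = unet.backward(params, info, dprob)
            if config.learning_rate:
                for p, g in zip(params, grads):
                    p -= config.learning_rate * g
        history.append(float(np.mean(losses)))
        if config.target_loss is not None and history[-1] < config.target_loss:
            break
    return params, history


# ---------------------------------------------------------------------------
# inference

def pad_to_valid(image_chw: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflect-pad (C, H, W) so H and W divide by 8; returns (padded, (H, W))."""
    _, h, w = image_chw.shape
    if h < DIVISOR or w < DIVISOR:
        raise ValueError(f"image must be at least {DIVISOR}x{DIVISOR}; got {h}x{w}")
    ph = (-h) % DIVISOR
    pw = (-w) % DIVISOR
    if ph == 0 and pw == 0:
        return image_chw, (h, w)
    padded = np.pad(image_chw, ((0, 0), (0, ph), (0, pw)), mode="reflect")
    return padded, (h, w)


def infer(params: list[np.ndarray], image: np.ndarray) -> np.ndarray:
    """Probability map for one RGB image (H, W, 3); output (H, W) in [0, 1].

    Sizes that do not divide by 8 are reflect-padded to the next multiple
    and the output is cropped back, so odd-sized search-range crops work.
    """
    x = _as_net_input(image)[0]
    xp, (h, w) = pad_to_valid(x)
    prob, _ = unet.forward(params, xp[None], want_cache=False)
    return prob[0, 0, :h, :w].astype(np.float64)


def infer_with_grad(params: list[np.ndarray], image: np.ndarray,
                    b_init: np.ndarray):
    """One forward/backward pass of the Soft Dice loss against ``b_init``.

    Used by the online relearning loop.  The loss is evaluated on the
    un-padded crop region only; gradients outside it are zero.
    Returns (prob_map (H, W), loss, parameter gradients).
    """
    x = _as_net_input(image)[0]
    xp, (h, w) = pad_to_valid(x)
    prob, info = unet.forward(params, xp[None])
    p_crop = prob[0, 0, :h, :w].astype(np.float64)
    loss, grad = _soft_dice_grad(p_crop, np.asarray(b_init, dtype=np.float64))
    dprob = np.zeros_like(prob)
    dprob[0, 0, :h, :w] = grad
    grads = unet.backward(params, info, dprob)
    return p_crop, loss, grads


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(path, params: list[np.ndarray], config: NetworkConfig,
                    metadata: dict | None = None) -> None:
    """Single-file ``.npz`` checkpoint embedding architecture + metadata."""
    meta = {
        "config": {"levels": config.levels,
                   "base_channels": config.base_channels,
                   "kernel_size": config.kernel_size,
                   "input_channels": config.input_channels,
                   "output_channels": config.output_channels},
        "metadata": metadata or {},
    }
    arrays = {f"p{i:03d}": p for i, p in enumerate(params)}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[list[np.ndarray], NetworkConfig, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        keys = sorted(k for k in data.files if k.startswith("p"))
        params = [data[k].copy() for k in keys]
    config = NetworkConfig(**meta["config"])
    expected = unet.param_shapes(config)
    got = [p.shape for p in params]
    if got != expected:
        raise ValueError("checkpoint parameter shapes do not match its config")
    return params, config, meta["metadata"]


# ---------------------------------------------------------------------------
# estimator

class UNetSegmenter(BaseEstimator):
    """Scikit-learn style wrapper around the U-Net apex segmenter.

    Parameters
    ----------
    base_channels : int
        Channel width of the first level; deeper levels double it.
    learning_rate, batch_size, epochs : SGD hyper-parameters.
    target_loss : float or None
        Optional early stop once the epoch-mean training loss drops below it.
    threshold : float
        Probability cut used by :meth:`predict`.
    seed : int
        Drives weight init and shuffling; same seed, same data => same model.

    Attributes (after :meth:`fit`)
    ------------------------------
    params_ : list of ndarray — trained parameters.
    loss_history_ : list of float — epoch-mean Soft Dice losses.
    config_ : NetworkConfig — the architecture actually built.
    """

    def __init__(self, base_channels: int = 16, learning_rate: float = 0.01,
                 batch_size: int = 8, epochs: int = 20,
                 target_loss: float | None = None,
                 threshold: float = 0.75, seed: int = 0):
        self.base_channels = base_channels
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.target_loss = target_loss
        self.threshold = threshold
        self.seed = seed

    def fit(self, X, y):
        """Train on frames ``X`` (n, H, W, 3) and binary masks ``y`` (n, H, W)."""
        X = np.asarray(X)
        y = np.asarray(y)
        if len(X) == 0:
            raise ValueError("training dataset is empty")
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        self.config_ = NetworkConfig(base_channels=self.base_channels)
        params = build_network(self.config_, self.seed)
        tc = TrainConfig(learning_rate=self.learning_rate,
                         batch_size=self.batch_size, epochs=self.epochs,
                         seed=self.seed, target_loss=self.target_loss)
        self.params_, self.loss_history_ = train(
            params, list(zip(X, y)), tc)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Probability map(s); accepts one (H, W, 3) image or a batch."""
        self._check_fitted()
        X = np.asarray(X)
        if X.ndim == 3:
            return infer(self.params_, X)
        return np.stack([infer(self.params_, img) for img in X])

    def predict(self, X) -> np.ndarray:
        """Binary segmentation at ``self.threshold``."""
        return (self.predict_proba(X) >= self.threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean (1 - Soft Dice loss) over pairs — higher is better."""
        probs = self.predict_proba(np.asarray(X))
        if probs.ndim == 2:
            probs = probs[None]
        return float(np.mean(
            [1.0 - soft_dice_loss(p, m) for p, m in zip(probs, np.asarray(y))]))

    def save(self, path) -> None:
        self._check_fitted()
        save_checkpoint(path, self.params_, self.config_,
                        {"loss_history": self.loss_history_})

    @classmethod
    def load(cls, path) -> "UNetSegmenter":
        params, config, meta = load_checkpoint(path)
        est = cls(base_channels=config.base_channels)
        est.config_ = config
        est.params_ = params
        est.loss_history_ = list(meta.get("loss_history", []))
        return est

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("UNetSegmenter is not fitted; call fit() or load()")
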