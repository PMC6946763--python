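"""Single U-Net nerve segmenter: config, Dice cost, training and prediction.

The segmenter maps a square greyscale patch to a same-shaped map of
foreground probabilities through a U-shaped encoder/decoder with skip
connections, trained with a soft Dice cost (1 - DSC).  ``UNetSegmenter``
wraps architecture + patching + training into a scikit-learn style
estimator operating on full images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .nn import Adam, UNet
from .patches import extract_patches, plan_grid, stitch_majority

__all__ = ["UNetConfig", "TrainConfig", "build_unet", "dice_coefficient",
           "soft_dice_loss", "train", "predict_patch", "UNetSegmenter"]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture of the segmenter.

    ``depth`` pooling levels halve the resolution each, so the input side
    must be divisible by ``2**depth`` (128 px patches with depth 4 hold).
    Channels double per level from ``base_channels``.
    """

    depth: int = 4
    base_channels: int = 32
    dropout_rate: float = 0.2
    conv_kernel: int = 3
    pool_kernel: int = 2
    final_activation: str = "sigmoid"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if self.base_channels < 1:
            raise ValueError(f"base_channels must be >= 1, got {self.base_channels}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings.  ``epochs`` defaults to a desk-scale 20."""

    epochs: int = 20
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    loss: str = "dice"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")


def build_unet(config: UNetConfig = UNetConfig(), seed: int = 0) -> UNet:
    """Instantiate a U-Net with seeded He-initialised weights."""
    return UNet(depth=config.depth, base_channels=config.base_channels,
                dropout_rate=config.dropout_rate, seed=seed)


def dice_coefficient(pred: np.ndarray, truth: np.ndarray,
                     smooth: float = 0.0) -> float:
    """Dice similarity coefficient (2|A.B| + s) / (|A| + |B| + s).

    With ``smooth == 0`` and two empty rasters the DSC is defined as 1
    (perfect agreement on emptiness).
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    num = 2.0 * float((pred * truth).sum()) + smooth
    den = float(pred.sum() + truth.sum()) + smooth
    if den == 0.0:
        return 1.0
    return num / den


def soft_dice_loss(pred: np.ndarray, truth: np.ndarray,
                   smooth: float = 1.0) -> tuple[float, np.ndarray]:
    """Differentiable Dice loss over a batch; returns (loss, dloss/dpred)."""
    pred = np.asarray(pred, dtype=np.float32)
    truth = np.asarray(truth, dtype=np.float32)
    num = 2.0 * (pred * truth).sum() + smooth
    den = pred.sum() + truth.sum() + smooth
    loss = 1.0 - num / den
    grad = -(2.0 * truth * den - num) / den ** 2
    return float(loss), grad.astype(np.float32)


def train(model: UNet, pairs: list[tuple[np.ndarray, np.ndarray]],
          cfg: TrainConfig = TrainConfig()) -> tuple[UNet, list[float]]:
    """Train a U-Net on (patch, mask) pairs with Adam and soft Dice loss.

    Deterministic given the model's init seed and ``cfg.seed`` (shuffling).
    Returns the model and the per-epoch mean loss trace.
    """
    if len(pairs) == 0:
        raise ValueError("empty training set")
    shuffle_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xC0FFEE)))
    opt = Adam(model.params, lr=cfg.learning_rate)
    xs = np.stack([np.asarray(p, dtype=np.float32) for p, _ in pairs])
    ys = np.stack([np.asarray(m, dtype=np.float32) for _, m in pairs])
    n = len(pairs)
    trace: list[float] = []
    for _ in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            pred = model.forward(xs[idx], training=True)
            loss, grad = soft_dice_loss(pred, ys[idx])
            model.backward(grad)
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return model, trace


def predict_patch(model: UNet, patch: np.ndarray) -> np.ndarray:
    """Forward one patch (or a stack) at inference; values in (0, 1)."""
    return model.forward(np.asarray(patch, dtype=np.float32), training=False)


def _pixels(obj) -> np.ndarray:
    return np.asarray(getattr(obj, "pixels", obj), dtype=np.float32)


class UNetSegmenter(BaseEstimator):
    """Patch-based U-Net segmenter for full CCM frames (sklearn estimator).

    ``fit(X, y)`` takes lists of greyscale images and binary masks (arrays or
    ``CCMImage``/``AnnotationMask``); frames are tiled into overlapping
    patches (default 128 px, stride 32), the U-Net is trained on the patch
    pairs, and ``predict`` stitches patch probabilities back into full-frame
    binary masks by majority voting.

    Attributes (after fit)
    ----------------------
    model_ : UNet            trained network
    loss_trace_ : list       per-epoch mean training Dice loss
    n_patches_ : int         number of training patch pairs
    """

    def __init__(self, depth: int = 4, base_channels: int = 32,
                 dropout_rate: float = 0.2, patch_px: int = 128,
                 stride_px: int = 32, epochs: int = 20, batch_size: int = 8,
                 learning_rate: float = 1e-3, threshold: float = 0.5,
                 stitch_mode: str = "vote", tie_positive: bool = True,
                 random_state: int = 0):
        self.depth = depth
        self.base_channels = base_channels
        self.dropout_rate = dropout_rate
        self.patch_px = patch_px
        self.stride_px = stride_px
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.threshold = threshold
        self.stitch_mode = stitch_mode
        self.tie_positive = tie_positive
        self.random_state = random_state

    # -- internal ---------------------------------------------------------
    def _configs(self) -> tuple[UNetConfig, TrainConfig]:
        return (UNetConfig(depth=self.depth, base_channels=self.base_channels,
                           dropout_rate=self.dropout_rate),
                TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                            learning_rate=self.learning_rate,
                            seed=self.random_state))

    def _patch_pairs(self, X, y) -> list[tuple[np.ndarray, np.ndarray]]:
        pairs = []
        for img, msk in zip(X, y):
            a, m = _pixels(img), _pixels(msk)
            if a.shape != m.shape:
                raise ValueError(f"image/mask shape mismatch: {a.shape} vs {m.shape}")
            grid = plan_grid(a.shape, self.patch_px, self.stride_px)
            pairs.extend(zip(extract_patches(a, grid), extract_patches(m, grid)))
        return pairs

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y) -> "UNetSegmenter":
        if len(X) == 0 or len(X) != len(y):
            raise ValueError("fit requires equal-length, non-empty X and y")
        unet_cfg, train_cfg = self._configs()
        pairs = self._patch_pairs(X, y)
        model = build_unet(unet_cfg, seed=self.random_state)
        model, trace = train(model, pairs, train_cfg)
        self.model_ = model
        self.loss_trace_ = trace
        self.n_patches_ = len(pairs)
        return self

    def _proba_one(self, img) -> list[np.ndarray]:
        a = _pixels(img)
        grid = plan_grid(a.shape, self.patch_px, self.stride_px)
        patches = np.stack(extract_patches(a, grid))
        probs = []
        for start in range(0, len(patches), self.batch_size):
            probs.append(predict_patch(self.model_, patches[start:start + self.batch_size]))
        return list(np.concatenate(probs)), grid

    def predict(self, X) -> list[np.ndarray]:
        """Full-frame binary masks, one uint8 array per input image."""
        self._check_fitted()
        out = []
        for img in X:
            probs, grid = self._proba_one(img)
            out.append(stitch_majority(probs, grid, mode=self.stitch_mode,
                                       tie_positive=self.tie_positive,
                                       threshold=self.threshold))
        return out

    def predict_proba(self, X) -> list[np.ndarray]:
        """Per-pixel mean foreground probability maps (coverage-averaged)."""
        self._check_fitted()
        out = []
        for img in X:
            probs, grid = self._proba_one(img)
            acc = np.zeros(grid.image_shape)
            cover = np.zeros(grid.image_shape)
            p = grid.patch_px
            for (r, c), patch in zip(grid.anchors, probs):
                acc[r:r + p, c:c + p] += patch
                cover[r:r + p, c:c + p] += 1
            out.append(acc / np.maximum(cover, 1))
        return out

    def score(self, X, y) -> float:
        """Mean hard Dice against reference masks."""
        preds = self.predict(X)
        return float(np.mean([dice_coefficient(p, _pixels(m) > 0.5)
                              for p, m in zip(preds, y)]))

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("UNetSegmenter is not fitted; call fit first")
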