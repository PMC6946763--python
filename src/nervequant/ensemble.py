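"""Bootstrap ensemble of U-Nets with pixel-wise majority-vote fusion.

Each of ``n_members`` (default 5, kept odd so no pixel tie is possible)
U-Nets is trained on an image-level sample-with-replacement resample of the
training set; member predictions are fused per pixel: foreground iff at
least ``ceil(n/2)`` members vote foreground.  Bootstrapping at the image
(not patch) level preserves image-level train/test hygiene.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator

from .unet import UNetSegmenter, _pixels

__all__ = ["bootstrap_sample", "train_ensemble", "predict_ensemble",
           "majority_vote", "EnsembleSegmenter"]


def bootstrap_sample(items: list, seed: int) -> list:
    """Image-level sample with replacement, same size, deterministic per seed."""
    if len(items) == 0:
        raise ValueError("cannot bootstrap an empty list")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(items), size=len(items))
    return [items[i] for i in idx]


def majority_vote(masks: list[np.ndarray]) -> np.ndarray:
    """Pixel-wise majority over member masks: 1 iff votes >= ceil(n/2)."""
    if len(masks) == 0:
        raise ValueError("majority_vote needs at least one mask")
    stack = np.stack([np.asarray(m) > 0 for m in masks])
    need = (len(masks) + 1) // 2
    return (stack.sum(axis=0) >= need).astype(np.uint8)


class EnsembleSegmenter(BaseEstimator):
    """Ensemble of ``UNetSegmenter`` members (sklearn estimator).

    Parameters mirror ``UNetSegmenter`` plus the ensemble settings.  Member
    seeds default to values derived from ``random_state``; each member
    differs both by its bootstrap resample and its weight-init seed, and the
    seed list is recorded in ``member_seeds_`` for full reproducibility.

    Attributes (after fit)
    ----------------------
    members_ : list of fitted UNetSegmenter
    member_seeds_ : list of int
    """

    def __init__(self, n_members: int = 5, member_seeds: list[int] | None = None,
                 bootstrap: bool = True, depth: int = 4, base_channels: int = 32,
                 dropout_rate: float = 0.2, patch_px: int = 128,
                 stride_px: int = 32, epochs: int = 20, batch_size: int = 8,
                 learning_rate: float = 1e-3, threshold: float = 0.5,
                 stitch_mode: str = "vote", tie_positive: bool = True,
                 random_state: int = 0):
        self.n_members = n_members
        self.member_seeds = member_seeds
        self.bootstrap = bootstrap
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

    def _resolve_seeds(self) -> list[int]:
        if self.member_seeds is not None:
            seeds = [int(s) for s in self.member_seeds]
            if len(seeds) != self.n_members:
                raise ValueError(f"member_seeds has {len(seeds)} entries for "
                                 f"{self.n_members} members")
        else:
            state = np.random.SeedSequence(self.random_state).generate_state(
                self.n_members)
            seeds = [int(s % (2 ** 31)) for s in state]
        if len(set(seeds)) != len(seeds):
            warnings.warn("duplicate member seeds: some ensemble members will "
                          "be identical", stacklevel=2)
        return seeds

    def fit(self, X, y) -> "EnsembleSegmenter":
        if self.n_members < 1 or self.n_members % 2 == 0:
            raise ValueError(f"n_members must be a positive odd count, "
                             f"got {self.n_members}")
        if len(X) == 0 or len(X) != len(y):
            raise ValueError("fit requires equal-length, non-empty X and y")
        seeds = self._resolve_seeds()
        pairs = list(zip(X, y))
        self.members_ = []
        for seed in seeds:
            sample = bootstrap_sample(pairs, seed) if self.bootstrap else pairs
            member = UNetSegmenter(
                depth=self.depth, base_channels=self.base_channels,
                dropout_rate=self.dropout_rate, patch_px=self.patch_px,
                stride_px=self.stride_px, epochs=self.epochs,
                batch_size=self.batch_size, learning_rate=self.learning_rate,
                threshold=self.threshold, stitch_mode=self.stitch_mode,
                tie_positive=self.tie_positive, random_state=seed)
            member.fit([p for p, _ in sample], [m for _, m in sample])
            self.members_.append(member)
        self.member_seeds_ = seeds
        return self

    def predict(self, X) -> list[np.ndarray]:
        """Majority-vote fused binary masks, one per input image."""
        if not hasattr(self, "members_"):
            raise RuntimeError("EnsembleSegmenter is not fitted; call fit first")
        member_masks = [m.predict(X) for m in self.members_]
        return [majority_vote([mm[i] for mm in member_masks])
                for i in range(len(X))]

    def score(self, X, y) -> float:
        from .unet import dice_coefficient

        preds = self.predict(X)
        return float(np.mean([dice_coefficient(p, _pixels(m) > 0.5)
                              for p, m in zip(preds, y)]))


def train_ensemble(images, masks, unet_cfg=None, train_cfg=None,
                   ens_cfg: dict | None = None) -> EnsembleSegmenter:
    """Functional wrapper: train an ensemble from config objects/dicts."""
    kwargs: dict = {}
    if unet_cfg is not None:
        kwargs.update(depth=unet_cfg.depth, base_channels=unet_cfg.base_channels,
                      dropout_rate=unet_cfg.dropout_rate)
    if train_cfg is not None:
        kwargs.update(epochs=train_cfg.epochs, batch_size=train_cfg.batch_size,
                      learning_rate=train_cfg.learning_rate,
                      random_state=train_cfg.seed)
    if ens_cfg:
        kwargs.update(ens_cfg)
    est = EnsembleSegmenter(**kwargs)
    return est.fit(images, masks)


def predict_ensemble(est: EnsembleSegmenter, image) -> np.ndarray:
    """Fused binary mask for a single standardized image."""
    return est.predict([image])[0]
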