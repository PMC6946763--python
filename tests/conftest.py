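"""Shared fixtures: phantom corpora and (for the end-to-end checks) trained
segmenters at desk scale.

The training fixture is session-scoped and deliberately small (192 px
phantoms, 64 px patches, shallow narrow U-Nets, few epochs): large enough
for the networks to clearly beat trivial baselines on held-out phantoms,
small enough to run on one CPU in a few minutes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from nervequant.synthetic import PhantomSpec, generate_phantom


TRAIN_SPEC = PhantomSpec(image_size=192)


def make_phantoms(n: int, spec: PhantomSpec = TRAIN_SPEC, seed0: int = 0):
    images, truths = [], []
    for k in range(n):
        img, truth = generate_phantom(dataclasses.replace(spec, seed=seed0 + k))
        images.append(img)
        truths.append(truth)
    return images, truths


@pytest.fixture(scope="session")
def phantom_corpus():
    """12 training + 4 held-out phantoms at 192 px."""
    train_images, train_truths = make_phantoms(12, seed0=100)
    test_images, test_truths = make_phantoms(4, seed0=900)
    return {
        "train_images": train_images,
        "train_masks": [t.mask for t in train_truths],
        "test_images": test_images,
        "test_truths": test_truths,
        "test_masks": [t.mask for t in test_truths],
    }


_SEG_KW = dict(depth=2, base_channels=8, patch_px=64, stride_px=32,
               epochs=6, batch_size=8, random_state=0)


@pytest.fixture(scope="session")
def trained_single(phantom_corpus):
    """A single U-Net (1-member pipeline) fitted on the phantom corpus."""
    from nervequant.unet import UNetSegmenter

    seg = UNetSegmenter(**_SEG_KW)
    seg.fit(phantom_corpus["train_images"], phantom_corpus["train_masks"])
    return seg


@pytest.fixture(scope="session")
def trained_ensemble(phantom_corpus):
    """A 5-member bootstrap ensemble fitted on the phantom corpus."""
    from nervequant.ensemble import EnsembleSegmenter

    est = EnsembleSegmenter(n_members=5, **_SEG_KW)
    est.fit(phantom_corpus["train_images"], phantom_corpus["train_masks"])
    return est
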