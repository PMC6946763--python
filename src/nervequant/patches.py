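"""Patch tiling and majority-vote stitching.

Full frames are tiled into overlapping square patches for the network
(default 128 px patches on a 32 px stride, giving 81 patches on a 384 px
frame) and patch-level segmentations are fused back into a full-frame mask
by per-pixel majority voting over the patches that cover each pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PatchGrid", "plan_grid", "extract_patches", "stitch_majority"]


@dataclass(frozen=True)
class PatchGrid:
    """Tiling layout linking patches to image pixels.

    ``anchors`` are the (row, col) top-left corners in row-major order; every
    patch lies fully inside ``image_shape``.
    """

    patch_px: int
    stride_px: int
    anchors: tuple[tuple[int, int], ...]
    image_shape: tuple[int, int]


def _axis_anchors(dim: int, patch: int, stride: int) -> list[int]:
    anchors = list(range(0, dim - patch + 1, stride))
    if anchors[-1] != dim - patch:  # flush anchor so the border is covered
        anchors.append(dim - patch)
    return anchors


def plan_grid(image_shape: tuple[int, int], patch_px: int = 128,
              stride_px: int = 32) -> PatchGrid:
    """Plan a row-major grid of fully-interior patch anchors.

    Anchors step by ``stride_px`` per axis from 0; if the last regular anchor
    does not flush the border, one extra anchor at ``dim - patch_px`` is
    appended so the frame is fully covered.
    """
    h, w = int(image_shape[0]), int(image_shape[1])
    if patch_px > min(h, w):
        raise ValueError(f"patch_px={patch_px} exceeds image shape {(h, w)}")
    if patch_px < 1 or stride_px < 1:
        raise ValueError("patch_px and stride_px must be >= 1")
    rows = _axis_anchors(h, patch_px, stride_px)
    cols = _axis_anchors(w, patch_px, stride_px)
    anchors = tuple((r, c) for r in rows for c in cols)
    return PatchGrid(patch_px=patch_px, stride_px=stride_px,
                     anchors=anchors, image_shape=(h, w))


def _as_array(image) -> np.ndarray:
    return np.asarray(getattr(image, "pixels", image))


def extract_patches(image, grid: PatchGrid) -> list[np.ndarray]:
    """Cut the patches of ``grid`` out of an image or mask, in anchor order."""
    arr = _as_array(image)
    if arr.shape != grid.image_shape:
        raise ValueError(f"image shape {arr.shape} does not match grid "
                         f"{grid.image_shape}")
    p = grid.patch_px
    return [arr[r:r + p, c:c + p] for r, c in grid.anchors]


def stitch_majority(patch_masks: list[np.ndarray], grid: PatchGrid,
                    mode: str = "vote", tie_positive: bool = True,
                    threshold: float = 0.5) -> np.ndarray:
    """Fuse patch-level segmentations into a full-frame binary mask.

    Parameters
    ----------
    patch_masks : list of ndarray
        One patch-sized raster per anchor.  In ``"vote"`` mode these are
        binarised at ``threshold`` and each patch casts one vote per covered
        pixel; a pixel is foreground iff positive votes reach a majority of
        the covering patches (ties count positive when ``tie_positive``).
        In ``"mean_prob"`` mode the raw values are averaged over covering
        patches and thresholded.
    """
    if len(patch_masks) != len(grid.anchors):
        raise ValueError(f"expected {len(grid.anchors)} patch masks, "
                         f"got {len(patch_masks)}")
    if mode not in ("vote", "mean_prob"):
        raise ValueError(f"unknown stitch mode {mode!r}")
    p = grid.patch_px
    acc = np.zeros(grid.image_shape, dtype=float)
    cover = np.zeros(grid.image_shape, dtype=np.int32)
    for (r, c), patch in zip(grid.anchors, patch_masks):
        patch = np.asarray(patch, dtype=float)
        if patch.shape != (p, p):
            raise ValueError(f"patch shape {patch.shape} != ({p}, {p})")
        if mode == "vote":
            acc[r:r + p, c:c + p] += (patch >= threshold)
        else:
            acc[r:r + p, c:c + p] += patch
        cover[r:r + p, c:c + p] += 1
    if mode == "vote":
        # v >= ceil(c/2)  <=>  2v >= c (tie positive) / 2v > c (tie negative)
        votes = np.round(acc).astype(np.int64)
        if tie_positive:
            return (2 * votes >= cover).astype(np.uint8) & (cover > 0).astype(np.uint8)
        return (2 * votes > cover).astype(np.uint8)
    with np.errstate(invalid="ignore"):
        mean = np.divide(acc, cover, out=np.zeros_like(acc), where=cover > 0)
    return (mean >= threshold).astype(np.uint8)
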