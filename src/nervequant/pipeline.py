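"""Workflow orchestration: dataset splits, batch quantification, validation.

This module glues the pieces together for the command line: image-level
(optionally subject-level) train/test splits, persisting and reloading
trained ensembles, running segmentation + morphometry over a directory of
images, and producing the agreement/ROC validation tables.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as nqio
from .ensemble import EnsembleSegmenter
from .morphometry import quantify
from .stats import bland_altman, error_summary, roc_analysis

__all__ = ["SplitPlan", "make_split", "save_ensemble", "load_ensemble",
           "run_quantify", "run_validate", "METRIC_COLUMNS"]

METRIC_COLUMNS = ["total_length_um", "n_branch", "n_tail", "n_segments",
                  "mean_segment_length_um", "sd_segment_length_um",
                  "fractal_number"]


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/test image id lists with the seed that produced them."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int
    split_fraction: float


def make_split(ids: list[str], fraction: float = 0.9, seed: int = 0,
               subject_ids: list[str] | None = None) -> SplitPlan:
    """Seeded permutation (Mersenne Twister) then prefix split at image level.

    With ``subject_ids`` given, whole subjects are assigned to one side so no
    acquisition session straddles the split.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if len(ids) < 2:
        raise ValueError("need at least 2 images to split")
    rng = np.random.Generator(np.random.MT19937(seed))
    if subject_ids is None:
        order = rng.permutation(len(ids))
        n_train = int(np.floor(fraction * len(ids)))
        train = [ids[i] for i in order[:n_train]]
        test = [ids[i] for i in order[n_train:]]
    else:
        if len(subject_ids) != len(ids):
            raise ValueError("subject_ids must match ids in length")
        subjects = sorted(set(subject_ids))
        perm = [subjects[i] for i in rng.permutation(len(subjects))]
        target = fraction * len(ids)
        train_subjects, n_assigned = set(), 0
        for s in perm:
            if n_assigned >= target:
                break
            train_subjects.add(s)
            n_assigned += sum(1 for x in subject_ids if x == s)
        train = [i for i, s in zip(ids, subject_ids) if s in train_subjects]
        test = [i for i, s in zip(ids, subject_ids) if s not in train_subjects]
    if not train or not test:
        raise ValueError("split fraction leaves one side empty")
    return SplitPlan(tuple(train), tuple(test), seed, fraction)


# -- model persistence ----------------------------------------------------

def save_ensemble(est: EnsembleSegmenter, out_dir: str | os.PathLike) -> str:
    """Persist a fitted ensemble: params manifest (JSON) + weight files (npz)."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    manifest = {"params": est.get_params(), "member_seeds": est.member_seeds_,
                "members": []}
    for k, member in enumerate(est.members_):
        path = os.path.join(out_dir, f"member_{k}.npz")
        np.savez(path, **{f"p{i}": p for i, (p, _) in
                          enumerate(member.model_.params)})
        manifest["members"].append(os.path.basename(path))
    mpath = os.path.join(out_dir, "ensemble.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return mpath


def load_ensemble(model_dir: str | os.PathLike) -> EnsembleSegmenter:
    """Reload a persisted ensemble ready for prediction."""
    from .unet import UNetSegmenter, build_unet, UNetConfig

    model_dir = os.fspath(model_dir)
    with open(os.path.join(model_dir, "ensemble.json")) as fh:
        manifest = json.load(fh)
    est = EnsembleSegmenter(**manifest["params"])
    est.member_seeds_ = manifest["member_seeds"]
    est.members_ = []
    for seed, fname in zip(est.member_seeds_, manifest["members"]):
        member = UNetSegmenter(
            depth=est.depth, base_channels=est.base_channels,
            dropout_rate=est.dropout_rate, patch_px=est.patch_px,
            stride_px=est.stride_px, epochs=est.epochs,
            batch_size=est.batch_size, learning_rate=est.learning_rate,
            threshold=est.threshold, stitch_mode=est.stitch_mode,
            tie_positive=est.tie_positive, random_state=seed)
        model = build_unet(UNetConfig(depth=est.depth,
                                      base_channels=est.base_channels,
                                      dropout_rate=est.dropout_rate), seed=seed)
        data = np.load(os.path.join(model_dir, fname))
        for i, (p, _) in enumerate(model.params):
            p[:] = data[f"p{i}"]
        member.model_ = model
        member.loss_trace_ = []
        member.n_patches_ = 0
        est.members_.append(member)
    return est


# -- batch quantification --------------------------------------------------

def _overlay(image_pixels: np.ndarray, skeleton) -> np.ndarray:
    """RGB overlay: centrelines red, branch points blue, tail points green."""
    rgb = np.stack([image_pixels] * 3, axis=-1)
    rgb[skeleton.skeleton > 0] = [1.0, 0.0, 0.0]
    for r, c in skeleton.tail_points:
        rgb[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2] = [0.0, 1.0, 0.0]
    for r, c in skeleton.branch_points:
        rgb[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2] = [0.0, 0.0, 1.0]
    return (np.clip(rgb, 0, 1) * 255).astype(np.uint8)


def run_quantify(image_paths: list[str], estimator: EnsembleSegmenter | None,
                 out_dir: str | os.PathLike,
                 field_of_view_um: tuple[float, float] | None = None,
                 pixel_size_um: float | None = None,
                 masks_are_input: bool = False,
                 write_overlays: bool = True) -> pd.DataFrame:
    """Segment (unless inputs are already masks) and quantify each image.

    Writes ``morphometry.csv`` (one row per image, the seven clinical
    variables) and per-image overlay PNGs; unreadable images are skipped
    with a warning.  Raises if every input fails.
    """
    import imageio.v3 as iio

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for path in image_paths:
        try:
            if masks_are_input:
                mask_obj = nqio.load_mask(path)
                mask = mask_obj.pixels
                pitch = pixel_size_um or nqio.TARGET_PIXEL_UM
                pixels = mask.astype(float)
                image_id = mask_obj.source_id
            else:
                img = nqio.load_image(path, field_of_view_um=field_of_view_um)
                if img.pixel_size_um is None and pixel_size_um is not None:
                    img.pixel_size_um = (pixel_size_um, pixel_size_um)
                img = nqio.standardise(img)
                mask = estimator.predict([img])[0]
                pitch = img.isotropic_pixel_um
                pixels = img.pixels
                image_id = img.source_id
        except (IOError, ValueError) as exc:
            warnings.warn(f"skipping {path}: {exc}", stacklevel=2)
            continue
        record, skeleton = quantify(mask, pitch, return_skeleton=True)
        rows.append({"image_id": image_id, **record.to_dict()})
        if write_overlays:
            iio.imwrite(os.path.join(out_dir, f"{image_id}_overlay.png"),
                        _overlay(pixels, skeleton))
    if not rows:
        raise ValueError("no input image could be processed")
    df = pd.DataFrame(rows, columns=["image_id"] + METRIC_COLUMNS)
    df.to_csv(os.path.join(out_dir, "morphometry.csv"), index=False)
    return df


def run_validate(quantify_csv: str, manual_csv: str,
                 labels_csv: str | None = None,
                 out_dir: str | os.PathLike = ".",
                 positive_label: str = "neuropathy") -> dict:
    """Per-variable agreement vs manual annotation (+ ROC on total length).

    The two measurement tables are joined on ``image_id``; each shared
    metric column gets an RMSE/SD error summary, ICC(2,1) and Bland-Altman
    limits.  With a labels table, total nerve length is scored against the
    binary group label by ROC/Youden analysis.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    method = pd.read_csv(quantify_csv)
    manual = pd.read_csv(manual_csv)
    merged = method.merge(manual, on="image_id", suffixes=("_method", "_manual"))
    if len(merged) < 3:
        raise ValueError(f"join on image_id produced only {len(merged)} rows")
    variables = [c for c in METRIC_COLUMNS if f"{c}_method" in merged
                 and f"{c}_manual" in merged]
    table = []
    for var in variables:
        a = merged[f"{var}_method"].to_numpy(float)
        b = merged[f"{var}_manual"].to_numpy(float)
        keep = np.isfinite(a) & np.isfinite(b)
        es = error_summary(a[keep], b[keep])
        rep = bland_altman(a[keep], b[keep])
        table.append({"variable": var, "n": es.n, "rmse": es.rmse, "sd": es.sd,
                      "mean_error": es.v_bar, "icc": rep.icc,
                      "icc_band": rep.icc_band, "ba_mean_diff": rep.ba_mean_diff,
                      "ba_loa_low": rep.ba_loa_low, "ba_loa_high": rep.ba_loa_high})
    agreement = pd.DataFrame(table)
    agreement.to_csv(os.path.join(out_dir, "agreement.csv"), index=False)
    result: dict = {"agreement": agreement}
    if labels_csv is not None:
        labels = pd.read_csv(labels_csv)
        joined = method.merge(labels, on="image_id")
        roc = roc_analysis(joined["total_length_um"].to_numpy(float),
                           joined["group_label"].to_numpy(),
                           positive_label=positive_label)
        pd.DataFrame({"threshold": roc.thresholds,
                      "sensitivity": roc.sensitivity,
                      "specificity": roc.specificity}
                     ).to_csv(os.path.join(out_dir, "roc_curve.csv"), index=False)
        result["roc"] = roc
        with open(os.path.join(out_dir, "validation.json"), "w") as fh:
            json.dump({"auc": roc.auc, "youden_j": roc.youden_j,
                       "optimal_cut": roc.optimal_cut,
                       "sens_at_cut": roc.sens_at_cut,
                       "spec_at_cut": roc.spec_at_cut,
                       "orientation": roc.orientation}, fh, indent=1)
    return result
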