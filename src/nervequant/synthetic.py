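"""Seeded generator of CCM-like nerve phantoms with exact ground truth.

The sub-basal nerve plexus appears in corneal confocal microscopy as bright,
gently curving fibres a few pixels wide that enter the field of view at its
borders, occasionally branch, and sit on a noisy, non-uniformly illuminated
background.  The generator emulates exactly that: each nerve tree is a
persistent random walk (Gaussian heading increments) seeded at a random
border point; branches inherit the parent position and deviate the heading
by a fixed angle plus noise.  Ground truth is carried as sub-pixel polylines,
so morphometric truth (total length, branch/tail/segment counts) is
independent of rasterisation.

Trees are drawn sequentially and a walker stops before touching previously
laid fibre: phantom trees never overlap, which keeps branch/tail truth
well-defined on the raster (crossings between independent trees would create
junctions absent from the generating polylines).

The binary mask is, by construction, the rasterised centreline dilated with a
disc of radius ``(fibre_width_px - 1) // 2``.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.ndimage import binary_dilation
from skimage.draw import line as _draw_line
from skimage.morphology import disk

from .io import CCMImage, save_image, save_mask

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "generate_cohort",
    "render_phantom",
    "save_phantom",
    "save_cohort",
    "DEFAULT_HEALTHY",
    "DEFAULT_NEUROPATHY",
]

# fixed rendering constants (not part of the morphometric ground truth)
_BACKGROUND_LEVEL = 0.30
_FIBRE_CONTRAST = 0.45
_BRANCH_ANGLE = 0.9  # radians, mean deviation of a daughter fibre
_BRANCH_ANGLE_SD = 0.15
_BRANCH_ANGLE_MIN = 0.6  # floor so the daughter stroke separates quickly
_BRANCH_ANGLE_MAX = 1.3
_BRANCH_GAP_STEPS = 6  # minimum steps between branch events on one walker
_CLEARANCE_PX = 3  # minimum gap kept between distinct fibre strokes
_MAX_WALKERS_PER_TREE = 12


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom image.

    Defaults emulate a healthy sub-basal plexus frame: a handful of long
    fibres in a 384x384 field at 1.04 um/px, 3 px wide, on a noisy background
    with a 30% peak-to-trough illumination gradient.
    """

    image_size: int = 384
    pixel_size_um: float = 1.04
    n_trees: int = 5
    branch_prob: float = 0.03
    step_len_px: float = 2.0
    curvature_sigma: float = 0.12
    fibre_width_px: int = 3
    noise_sigma: float = 0.08
    illum_gradient: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size <= 0:
            raise ValueError(f"image_size must be > 0, got {self.image_size}")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.n_trees < 0:
            raise ValueError(f"n_trees must be >= 0, got {self.n_trees}")
        if not 0 <= self.branch_prob < 1:
            raise ValueError(f"branch_prob must be in [0, 1), got {self.branch_prob}")
        if self.step_len_px <= 0:
            raise ValueError(f"step_len_px must be > 0, got {self.step_len_px}")
        if self.curvature_sigma < 0:
            raise ValueError(f"curvature_sigma must be >= 0, got {self.curvature_sigma}")
        if self.fibre_width_px < 1:
            raise ValueError(f"fibre_width_px must be >= 1, got {self.fibre_width_px}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if not 0 <= self.illum_gradient <= 1:
            raise ValueError(f"illum_gradient must be in [0, 1], got {self.illum_gradient}")


DEFAULT_HEALTHY = PhantomSpec()
#: fewer, shorter trees: the fibre-loss phenotype of diabetic neuropathy
DEFAULT_NEUROPATHY = replace(DEFAULT_HEALTHY, n_trees=2, branch_prob=0.02)


@dataclass
class PhantomTruth:
    """Ground truth of a phantom: mask, polylines and morphometric truth."""

    mask: np.ndarray
    centreline_polylines: list[np.ndarray]
    true_total_length_um: float
    true_n_branch: int
    true_n_tail: int
    true_n_segments: int

    def to_json_dict(self) -> dict:
        return {
            "true_total_length_um": self.true_total_length_um,
            "true_n_branch": self.true_n_branch,
            "true_n_tail": self.true_n_tail,
            "true_n_segments": self.true_n_segments,
            "centreline_polylines": [p.tolist() for p in self.centreline_polylines],
        }


def _polyline_length_px(poly: np.ndarray) -> float:
    if len(poly) < 2:
        return 0.0
    return float(np.sum(np.hypot(*np.diff(poly, axis=0).T)))


class _Walker:
    __slots__ = ("points", "heading", "alive", "age", "grace",
                 "pending_junction", "parent", "last_branch_age")

    def __init__(self, start: np.ndarray, heading: float, grace: int,
                 parent: int | None = None):
        self.points: list[np.ndarray] = [np.asarray(start, dtype=float)]
        self.heading = float(heading)
        self.alive = True
        self.age = 0
        self.grace = grace  # steps during which own-tree collisions are ignored
        self.pending_junction: np.ndarray | None = None
        self.parent = parent  # index into the tree's walker list
        self.last_branch_age = 0


def _stamp(occ: np.ndarray, point: np.ndarray, radius: int) -> None:
    r, c = int(round(point[0])), int(round(point[1]))
    size = occ.shape[0]
    r0, r1 = max(r - radius, 0), min(r + radius + 1, size)
    c0, c1 = max(c - radius, 0), min(c + radius + 1, size)
    occ[r0:r1, c0:c1] = True


def _grow_tree(spec: PhantomSpec, rng: np.random.Generator,
               occ_other: np.ndarray) -> tuple[list[np.ndarray], int, int]:
    """Grow one nerve tree; returns (polylines, n_branch, n_tail).

    ``occ_other`` holds the dilated footprint of all previously drawn trees;
    the new tree is stamped into it as it grows.
    """
    size = spec.image_size
    clearance = spec.fibre_width_px + _CLEARANCE_PX
    delay = int(np.ceil((clearance + 1) / spec.step_len_px)) + 1
    grace = delay + 1
    max_steps = int(2.2 * size / spec.step_len_px)

    # entry point on a random border, heading roughly inward
    side = rng.integers(0, 4)
    t = rng.uniform(0, size - 1)
    if side == 0:  # top
        start, inward = np.array([0.0, t]), np.pi / 2
    elif side == 1:  # bottom
        start, inward = np.array([size - 1.0, t]), -np.pi / 2
    elif side == 2:  # left
        start, inward = np.array([t, 0.0]), 0.0
    else:  # right
        start, inward = np.array([t, size - 1.0]), np.pi
    heading = inward + rng.uniform(-0.6, 0.6)

    occ_own = np.zeros_like(occ_other)
    root = _Walker(start, heading, grace=0)
    walkers = [root]
    queue = [root]
    junctions: list[np.ndarray] = []  # branch nodes of surviving children

    while queue:
        w = queue.pop(0)
        while w.alive and w.age < max_steps:
            w.heading += rng.normal(0.0, spec.curvature_sigma)
            step = spec.step_len_px * np.array([np.sin(w.heading), np.cos(w.heading)])
            cand = w.points[-1] + step
            if not (0 <= cand[0] <= size - 1 and 0 <= cand[1] <= size - 1):
                break
            ri, ci = int(round(cand[0])), int(round(cand[1]))
            if occ_other[ri, ci]:
                break
            if occ_own[ri, ci]:
                # the grace exemption only covers the junction's immediate
                # neighbourhood, so a daughter can emerge from the parent
                # stroke but never cross an older trail of its own tree
                near_start = (np.hypot(*(cand - w.points[0])) <= clearance + 1)
                if w.age >= w.grace or not near_start:
                    break
            w.points.append(cand)
            w.age += 1
            # stamp own trail with a delay so the walker never collides
            # with the fibre it is currently laying
            if w.age > delay:
                _stamp(occ_own, w.points[w.age - delay], clearance)
            if (len(walkers) < _MAX_WALKERS_PER_TREE
                    and w.age > grace
                    and w.age - w.last_branch_age >= _BRANCH_GAP_STEPS
                    and rng.random() < spec.branch_prob):
                sign = 1.0 if rng.random() < 0.5 else -1.0
                angle = np.clip(_BRANCH_ANGLE + rng.normal(0.0, _BRANCH_ANGLE_SD),
                                _BRANCH_ANGLE_MIN, _BRANCH_ANGLE_MAX)
                child = _Walker(cand, w.heading + sign * angle,
                                grace=grace, parent=walkers.index(w))
                child.pending_junction = cand.copy()
                child.last_branch_age = 0
                w.last_branch_age = w.age
                walkers.append(child)
                queue.append(child)
        w.alive = False

    # keep only fibres that stay visible outside the parent's dilated
    # stroke: long enough, and (for daughters) escaping the parent path by
    # more than the stroke width.  A dropped walker drops its whole subtree
    # so polyline truth and raster stay consistent.
    min_points = int(np.ceil((2 * spec.fibre_width_px + 4) / spec.step_len_px)) + 1
    visible_dist = spec.fibre_width_px + 2.0
    kept = [False] * len(walkers)
    for k, w in enumerate(walkers):
        parent_ok = (w.parent is None) or kept[w.parent]
        ok = parent_ok and len(w.points) >= min_points
        if ok and w.parent is not None:
            ppts = np.asarray(walkers[w.parent].points)
            cpts = np.asarray(w.points)
            d2 = ((cpts[:, None, :] - ppts[None, :, :]) ** 2).sum(axis=2)
            ok = bool(np.sqrt(d2.min(axis=1)).max() >= visible_dist)
        kept[k] = ok
    if not kept[0]:
        return [], 0, 0  # root too short: no tree
    survivors = [w for k, w in enumerate(walkers) if kept[k]]
    polylines = [np.asarray(w.points) for w in survivors]

    for w in survivors:
        if w.pending_junction is not None:
            junctions.append(w.pending_junction)

    # a junction at a parent's terminal point is a continuation, not a branch
    end_points = [w.points[-1] for w in survivors]
    n_branch = 0
    degenerate_ends = set()
    for j in junctions:
        hit = [k for k, e in enumerate(end_points) if np.allclose(e, j)]
        if hit:
            degenerate_ends.update(hit)
        else:
            n_branch += 1
    n_tail = 1 + sum(1 for k in range(len(survivors)) if k not in degenerate_ends)
    # stamp the freshest (not yet stamped) trail into the shared occupancy
    for poly in polylines:
        for p in poly:
            _stamp(occ_other, p, clearance)
    return polylines, n_branch, n_tail


def _rasterise_centreline(polylines: list[np.ndarray], size: int) -> np.ndarray:
    centre = np.zeros((size, size), dtype=bool)
    for poly in polylines:
        pts = np.clip(np.round(poly).astype(int), 0, size - 1)
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = _draw_line(r0, c0, r1, c1)
            centre[rr, cc] = True
    return centre


def _render_image(centre: np.ndarray, spec: PhantomSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """Fibre Gaussian profile + constant background + low-frequency gradient
    + i.i.d. Gaussian noise, clipped to [0, 1]."""
    size = spec.image_size
    if centre.any():
        d = distance_transform_edt(~centre)
    else:
        d = np.full((size, size), np.inf)
    sigma = max(spec.fibre_width_px / 2.0, 0.8)
    fibre = _FIBRE_CONTRAST * np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    # tilted-plane illumination field with random orientation, peak-to-trough
    # amplitude = illum_gradient fraction of the background level
    theta = rng.uniform(0, 2 * np.pi)
    rr, cc = np.mgrid[0:size, 0:size] / max(size - 1, 1)
    ramp = rr * np.sin(theta) + cc * np.cos(theta)
    ramp = (ramp - ramp.min()) / max(ramp.max() - ramp.min(), 1e-12)
    background = _BACKGROUND_LEVEL * (1.0 + spec.illum_gradient * (ramp - 0.5))
    noise = rng.normal(0.0, spec.noise_sigma, (size, size))
    return np.clip(background + fibre + noise, 0.0, 1.0)


def render_phantom(polylines: list[np.ndarray], spec: PhantomSpec,
                   n_branch: int = 0, n_tail: int | None = None,
                   n_segments: int | None = None) -> tuple[CCMImage, PhantomTruth]:
    """Render an image + truth from explicit centreline polylines.

    Counts default to treating every polyline as an isolated unbranched
    fibre (two tails, one segment each); pass explicit counts otherwise.
    """
    polylines = [np.asarray(p, dtype=float) for p in polylines if len(p) >= 2]
    size = spec.image_size
    for poly in polylines:
        if poly.min() < 0 or poly.max() > size - 1:
            raise ValueError("polyline point outside the image frame")
    centre = _rasterise_centreline(polylines, size)
    radius = (spec.fibre_width_px - 1) // 2
    mask = binary_dilation(centre, structure=disk(radius)) if radius > 0 else centre
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0x9E37)))
    image = CCMImage(pixels=_render_image(centre, spec, rng),
                     pixel_size_um=(spec.pixel_size_um, spec.pixel_size_um),
                     source_id=f"phantom-{spec.seed}")
    total_um = sum(_polyline_length_px(p) for p in polylines) * spec.pixel_size_um
    truth = PhantomTruth(
        mask=mask,
        centreline_polylines=polylines,
        true_total_length_um=float(total_um),
        true_n_branch=n_branch,
        true_n_tail=(2 * len(polylines) if n_tail is None else n_tail),
        true_n_segments=(len(polylines) if n_segments is None else n_segments),
    )
    return image, truth


def generate_phantom(spec: PhantomSpec) -> tuple[CCMImage, PhantomTruth]:
    """Generate one phantom image and its ground truth.

    Deterministic for a fixed spec: tree k is driven by the k-th child of
    ``SeedSequence(spec.seed)``, so adding trees never alters existing ones
    (total true length is non-decreasing in ``n_trees``).
    """
    size = spec.image_size
    occ = np.zeros((size, size), dtype=bool)
    tree_seeds = np.random.SeedSequence(spec.seed).spawn(max(spec.n_trees, 1))
    polylines: list[np.ndarray] = []
    n_branch = n_tail = n_trees_grown = 0
    for k in range(spec.n_trees):
        rng_k = np.random.default_rng(tree_seeds[k])
        tree_polys, b, t = _grow_tree(spec, rng_k, occ)
        if not tree_polys:
            continue
        polylines.extend(tree_polys)
        n_branch += b
        n_tail += t
        n_trees_grown += 1
    n_segments = n_branch + n_tail - n_trees_grown if n_trees_grown else 0
    return render_phantom(polylines, spec, n_branch=n_branch, n_tail=n_tail,
                          n_segments=n_segments)


def generate_cohort(spec_healthy: PhantomSpec, spec_neuropathy: PhantomSpec,
                    n_per_group: int, seed: int
                    ) -> list[tuple[CCMImage, PhantomTruth, str]]:
    """Generate a labelled two-group cohort of phantoms.

    Per-image seeds derive from (spec.seed, cohort seed, index), so two
    groups with identical specs produce identical images.
    """
    if n_per_group < 1:
        raise ValueError(f"n_per_group must be >= 1, got {n_per_group}")
    out: list[tuple[CCMImage, PhantomTruth, str]] = []
    for label, spec in (("healthy", spec_healthy), ("neuropathy", spec_neuropathy)):
        for i in range(n_per_group):
            sub = int(np.random.SeedSequence((spec.seed, seed, i)).generate_state(1)[0]
                      % (2 ** 31))
            img, truth = generate_phantom(replace(spec, seed=sub))
            img = dataclasses.replace(img, source_id=f"{label}-{i:03d}")
            out.append((img, truth, label))
    return out


def save_phantom(image: CCMImage, truth: PhantomTruth, out_dir: str | os.PathLike,
                 stem: str) -> dict[str, str]:
    """Write image (PNG), mask (0/255 PNG) and truth (JSON sidecar)."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "image": os.path.join(out_dir, f"{stem}.png"),
        "mask": os.path.join(out_dir, f"{stem}_mask.png"),
        "truth": os.path.join(out_dir, f"{stem}_truth.json"),
    }
    save_image(image, paths["image"])
    save_mask(truth.mask, paths["mask"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_json_dict(), fh)
    return paths


def save_cohort(cohort: list[tuple[CCMImage, PhantomTruth, str]],
                out_dir: str | os.PathLike) -> str:
    """Write a cohort to disk plus a CSV manifest; returns the manifest path."""
    import csv

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    manifest = os.path.join(out_dir, "manifest.csv")
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_path", "mask_path", "group_label", "image_id",
                         "true_total_length_um"])
        for image, truth, label in cohort:
            stem = image.source_id or f"img-{id(image):x}"
            paths = save_phantom(image, truth, out_dir, stem)
            writer.writerow([paths["image"], paths["mask"], label, stem,
                             truth.true_total_length_um])
    return manifest
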