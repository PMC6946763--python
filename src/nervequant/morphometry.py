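"""Clinical nerve morphometry from a binary segmentation.

A segmented nerve mask is thinned to a 1-px skeleton; skeleton pixels are
classified by their 8-neighbour count (1 neighbour = tail/terminal point,
>= 3 neighbours = branch point, adjacent branch pixels merged into one
node); maximal node-free paths between nodes form the nerve segments.  From
these the seven per-image clinical variables are derived: total corneal
nerve fibre length (um), branch/tail/segment counts, mean and SD segment
length, and the box-counting fractal number.

Length measurement: the public ``path_length_um`` uses chamfer step
counting (orthogonal step 1, diagonal sqrt(2)).  For the aggregate record,
``quantify`` defaults to the Kulpa-calibrated step weights (0.9481 /
1.3408), which remove the systematic ~5% overestimate that chamfer
counting suffers on digital lines of arbitrary orientation; the chamfer
convention remains available via ``length_weights="chamfer"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve, label
from skimage.morphology import thin as _sk_thin

__all__ = ["NerveSkeleton", "MorphometryRecord", "skeletonize",
           "classify_nodes", "extract_segments", "path_length_um",
           "fractal_number", "quantify"]

_NEIGH_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

# step weights: (orthogonal, diagonal)
_WEIGHTS = {
    "chamfer": (1.0, math.sqrt(2.0)),
    "calibrated": (0.9481, 1.3408),  # Kulpa's unbiased digital-line weights
}


@dataclass
class NerveSkeleton:
    """1-px centreline raster with classified nodes and segments."""

    skeleton: np.ndarray
    branch_points: list[tuple[int, int]]
    tail_points: list[tuple[int, int]]
    segments: list[list[tuple[int, int]]]
    pixel_size_um: float


@dataclass
class MorphometryRecord:
    """The per-image clinical nerve variables."""

    total_length_um: float
    n_branch: int
    n_tail: int
    n_segments: int
    mean_segment_length_um: float
    sd_segment_length_um: float
    fractal_number: float  # NaN for an empty mask (dimension undefined)

    def to_dict(self) -> dict:
        return {
            "total_length_um": self.total_length_um,
            "n_branch": self.n_branch,
            "n_tail": self.n_tail,
            "n_segments": self.n_segments,
            "mean_segment_length_um": self.mean_segment_length_um,
            "sd_segment_length_um": self.sd_segment_length_um,
            "fractal_number": self.fractal_number,
        }

    def density_mm_per_mm2(self, field_area_mm2: float) -> float:
        """Convenience: CNF density = total length / field area."""
        return (self.total_length_um / 1000.0) / field_area_mm2


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Thin a binary mask to a 1-px-wide, connectivity-preserving skeleton.

    Morphological thinning to convergence is used (rather than the
    Zhang-Suen pass) because it never leaves 2x2 foreground blocks at
    junctions, which the node classifier relies on.
    """
    mask = np.asarray(mask) > 0
    return _sk_thin(mask)


def _neighbour_counts(skel: np.ndarray) -> np.ndarray:
    return convolve(skel.astype(np.uint8), _NEIGH_KERNEL, mode="constant")


def _has_2x2_block(skel: np.ndarray) -> bool:
    s = skel.astype(np.uint8)
    return bool(np.any(s[:-1, :-1] & s[1:, :-1] & s[:-1, 1:] & s[1:, 1:]))


def classify_nodes(skel: np.ndarray
                   ) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Branch and tail points of a 1-px skeleton.

    A tail point has exactly one 8-neighbour on; a branch point has >= 3.
    8-connected clusters of branch pixels (raster thinning yields 2-px
    clusters at crossings) are merged to a single point: the member pixel
    closest to the cluster centroid, ties broken lexicographically.
    """
    skel = np.asarray(skel) > 0
    if _has_2x2_block(skel):
        raise ValueError("input is not a 1-px skeleton (2x2 foreground block found)")
    counts = _neighbour_counts(skel)
    tails = [tuple(p) for p in np.argwhere(skel & (counts == 1))]
    branch_mask = skel & (counts >= 3)
    labels, n_lab = label(branch_mask, structure=np.ones((3, 3)))
    branch: list[tuple[int, int]] = []
    for k in range(1, n_lab + 1):
        members = np.argwhere(labels == k)
        centroid = members.mean(axis=0)
        d = np.abs(members - centroid).sum(axis=1)
        order = np.lexsort((members[:, 1], members[:, 0], d))
        branch.append(tuple(members[order[0]]))
    return sorted(branch), sorted(map(tuple, tails))


def _neighbours(p: tuple[int, int], skel: np.ndarray) -> list[tuple[int, int]]:
    h, w = skel.shape
    out = []
    for dr, dc in _OFFSETS:
        r, c = p[0] + dr, p[1] + dc
        if 0 <= r < h and 0 <= c < w and skel[r, c]:
            out.append((r, c))
    return out


def extract_segments(skel: np.ndarray,
                     nodes: tuple[list, list] | None = None
                     ) -> list[list[tuple[int, int]]]:
    """Maximal node-free 8-connected paths between nodes, plus loops.

    Node pixels are all branch-cluster pixels and all tail pixels.  Each
    segment is an ordered pixel path including its terminal node pixels;
    node-free cycles are reported as one closed segment each (first pixel
    repeated at the end).  Ordering is lexicographic by start pixel.
    """
    skel = np.asarray(skel) > 0
    counts = _neighbour_counts(skel)
    node_mask = skel & ((counts == 1) | (counts >= 3))
    node_pixels = [tuple(p) for p in np.argwhere(node_mask)]
    visited = np.zeros_like(skel, dtype=bool)
    segments: list[list[tuple[int, int]]] = []

    def is_node(p):
        return node_mask[p]

    edge_seen: set[frozenset] = set()
    for u in node_pixels:
        for v in _neighbours(u, skel):
            if is_node(v):
                # direct node-node contact: a 2-px segment, unless both sit
                # in the same branch cluster (counts >= 3 on both, adjacent)
                if counts[u] >= 3 and counts[v] >= 3:
                    continue
                key = frozenset((u, v))
                if key not in edge_seen:
                    edge_seen.add(key)
                    segments.append([u, v])
                continue
            if visited[v]:
                continue
            path = [u, v]
            visited[v] = True
            prev, cur = u, v
            while True:
                nxt = [q for q in _neighbours(cur, skel) if q != prev]
                # drop neighbours already inside this path's tail (diagonal
                # double-adjacency next to the previous pixel)
                nxt = [q for q in nxt
                       if q not in (path[-3:-1] if len(path) >= 3 else [])]
                step = None
                for q in nxt:
                    if is_node(q):
                        step = q
                        break
                if step is None:
                    cand = [q for q in nxt if not visited[q]]
                    if not cand:
                        break  # dead end (should not happen on clean skeletons)
                    step = cand[0]
                path.append(step)
                if is_node(step):
                    break
                visited[step] = True
                prev, cur = cur, step
            segments.append(path)

    # node-free cycles: remaining unvisited non-node pixels
    remaining = skel & ~visited & ~node_mask
    for start in map(tuple, np.argwhere(remaining)):
        if visited[start]:
            continue
        nbrs = _neighbours(start, skel)
        if not nbrs:  # isolated pixel: zero-length segment
            visited[start] = True
            segments.append([start])
            continue
        path = [start]
        visited[start] = True
        prev, cur = None, start
        while True:
            nxt = [q for q in _neighbours(cur, skel)
                   if q != prev and not visited[q]]
            if not nxt:
                break
            step = nxt[0]
            path.append(step)
            visited[step] = True
            prev, cur = cur, step
        if len(path) > 2 and path[0] in _neighbours(path[-1], skel):
            path.append(path[0])  # close the loop
        segments.append(path)

    # de-duplicate walks that started from both end nodes of one segment
    unique: dict[tuple, list] = {}
    for seg in segments:
        key = tuple(seg) if tuple(seg) <= tuple(reversed(seg)) else tuple(reversed(seg))
        unique.setdefault(key, seg)
    return sorted(unique.values(), key=lambda s: (s[0], s[-1], len(s)))


def path_length_um(path: list[tuple[int, int]], pixel_size_um: float,
                   weights: str | tuple[float, float] = "chamfer") -> float:
    """Geodesic length of an 8-connected pixel path in micrometres.

    Orthogonal steps count ``weights[0]``, diagonal steps ``weights[1]``
    (default chamfer 1 / sqrt(2)); a single pixel has zero length.
    """
    w_orth, w_diag = _WEIGHTS[weights] if isinstance(weights, str) else weights
    pts = np.asarray(path)
    if len(pts) < 2:
        return 0.0
    d = np.abs(np.diff(pts, axis=0))
    cheb = d.max(axis=1)
    if np.any(cheb != 1):
        raise ValueError("consecutive path pixels must be 8-adjacent")
    diag = d.min(axis=1) == 1
    return float((np.sum(~diag) * w_orth + np.sum(diag) * w_diag) * pixel_size_um)


def fractal_number(skeleton: np.ndarray) -> float:
    """Box-counting fractal dimension of a binary raster.

    Occupied boxes N(eps) are counted on grid-aligned partitions for dyadic
    box sizes eps in {2, 4, ..., min(shape)/4}; the returned value is the
    least-squares slope of log N against log(1/eps).
    """
    skel = np.asarray(skeleton) > 0
    if not skel.any():
        raise ValueError("fractal dimension undefined for an empty raster")
    max_eps = min(skel.shape) // 4
    sizes = []
    eps = 2
    while eps <= max_eps:
        sizes.append(eps)
        eps *= 2
    if len(sizes) < 2:
        raise ValueError(f"raster too small for box counting: {skel.shape}")
    counts = []
    for eps in sizes:
        h = -(-skel.shape[0] // eps) * eps
        w = -(-skel.shape[1] // eps) * eps
        padded = np.zeros((h, w), dtype=bool)
        padded[:skel.shape[0], :skel.shape[1]] = skel
        blocks = padded.reshape(h // eps, eps, w // eps, eps).any(axis=(1, 3))
        counts.append(int(blocks.sum()))
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes, dtype=float)),
                       np.log(np.asarray(counts, dtype=float)), 1)[0]
    return float(slope)


def quantify(mask: np.ndarray, pixel_size_um: float,
             length_weights: str | tuple[float, float] = "calibrated",
             return_skeleton: bool = False):
    """Full morphometry of a binary nerve mask.

    Composes skeletonisation, node classification, segment extraction and
    per-segment length measurement.  An empty mask yields an all-zero record
    with ``fractal_number = NaN``.
    """
    if pixel_size_um is None or pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be a known positive pitch")
    mask = np.asarray(mask) > 0
    if not mask.any():
        record = MorphometryRecord(0.0, 0, 0, 0, 0.0, 0.0, float("nan"))
        if return_skeleton:
            return record, NerveSkeleton(np.zeros_like(mask), [], [], [],
                                         pixel_size_um)
        return record
    skel = skeletonize(mask)
    branch, tails = classify_nodes(skel)
    segments = extract_segments(skel)
    lengths = np.array([path_length_um(s, pixel_size_um, weights=length_weights)
                        for s in segments])
    total = float(lengths.sum())
    mean = float(lengths.mean()) if len(lengths) else 0.0
    sd = float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0
    record = MorphometryRecord(
        total_length_um=total,
        n_branch=len(branch),
        n_tail=len(tails),
        n_segments=len(segments),
        mean_segment_length_um=mean,
        sd_segment_length_um=sd,
        fractal_number=fractal_number(skel),
    )
    if return_skeleton:
        return record, NerveSkeleton(skel, branch, tails, segments, pixel_size_um)
    return record
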