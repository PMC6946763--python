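"""Skeleton morphometry: thinning, node classification, segments, lengths,
box-counting fractal dimension, and ground-truth recovery on phantoms."""

import math

import numpy as np
import pytest

from nervequant.morphometry import (classify_nodes, extract_segments,
                                    fractal_number, path_length_um, quantify,
                                    skeletonize)
from nervequant.synthetic import PhantomSpec, generate_phantom, render_phantom


def _y_shape(size=21):
    """Three 1-px arms meeting at the centre pixel."""
    s = np.zeros((size, size), dtype=bool)
    c = size // 2
    s[c, :c + 1] = True          # west arm
    for k in range(1, c + 1):    # north-east and south-east arms
        s[c - k, c + k] = True
        s[c + k, c + k] = True
    return s


def _ring(r=8, size=24):
    s = np.zeros((size, size), dtype=bool)
    t = np.linspace(0, 2 * np.pi, 200)
    rr = np.round(size / 2 + r * np.sin(t)).astype(int)
    cc = np.round(size / 2 + r * np.cos(t)).astype(int)
    s[rr, cc] = True
    return skeletonize(s)  # canonical 1-px ring


class TestSkeletonize:
    def test_empty_in_empty_out(self):
        assert not skeletonize(np.zeros((16, 16), dtype=bool)).any()

    def test_wide_bar_thins_to_centre_line(self):
        mask = np.zeros((24, 60), dtype=bool)
        mask[10:13, 5:51] = True
        skel = skeletonize(mask)
        rows, cols = np.where(skel)
        assert set(rows) == {11}
        assert abs(cols.min() - 5) <= 1 and abs(cols.max() - 50) <= 1
        # 1-px wide: no 2x2 block
        s = skel.astype(np.uint8)
        assert not np.any(s[:-1, :-1] & s[1:, :-1] & s[:-1, 1:] & s[1:, 1:])

    def test_idempotent_on_thin_path(self):
        path = np.zeros((16, 16), dtype=bool)
        path[8, 2:14] = True
        assert np.array_equal(skeletonize(path), path)


class TestClassifyNodes:
    def test_straight_line(self):
        s = np.zeros((8, 20), dtype=bool)
        s[4, 3:17] = True
        branch, tails = classify_nodes(s)
        assert branch == []
        assert tails == [(4, 3), (4, 16)]

    def test_y_shape(self):
        branch, tails = classify_nodes(_y_shape())
        assert len(branch) == 1 and len(tails) == 3
        assert branch[0] == (10, 10)

    def test_ring_has_no_nodes(self):
        branch, tails = classify_nodes(_ring())
        assert branch == [] and tails == []

    def test_non_thinned_input_rejected(self):
        blob = np.zeros((8, 8), dtype=bool)
        blob[2:5, 2:5] = True
        with pytest.raises(ValueError, match="2x2"):
            classify_nodes(blob)


class TestExtractSegments:
    def test_straight_line_single_segment(self):
        s = np.zeros((8, 20), dtype=bool)
        s[4, 3:17] = True
        segs = extract_segments(s)
        assert len(segs) == 1
        assert len(segs[0]) == 14

    def test_y_shape_three_segments(self):
        segs = extract_segments(_y_shape())
        assert len(segs) == 3
        # every segment ends at the junction or a tail
        for seg in segs:
            assert (10, 10) in (seg[0], seg[-1])

    def test_two_disjoint_lines(self):
        s = np.zeros((12, 20), dtype=bool)
        s[3, 2:18] = True
        s[9, 2:18] = True
        assert len(extract_segments(s)) == 2

    def test_ring_is_one_closed_segment(self):
        segs = extract_segments(_ring())
        assert len(segs) == 1
        assert segs[0][0] == segs[0][-1]  # closed loop


class TestPathLength:
    def test_horizontal_path(self):
        path = [(5, c) for c in range(10, 20)]
        assert path_length_um(path, 1.04) == pytest.approx(9 * 1.04)

    def test_diagonal_path(self):
        path = [(k, k) for k in range(10)]
        assert path_length_um(path, 1.04) == pytest.approx(9 * math.sqrt(2) * 1.04)

    def test_single_pixel_zero(self):
        assert path_length_um([(3, 3)], 1.04) == 0.0

    def test_non_adjacent_rejected(self):
        with pytest.raises(ValueError, match="8-adjacent"):
            path_length_um([(0, 0), (0, 2)], 1.0)

    def test_calibrated_weights_shrink_diagonals(self):
        path = [(k, k) for k in range(10)]
        assert path_length_um(path, 1.0, weights="calibrated") == \
            pytest.approx(9 * 1.3408)


class TestFractalNumber:
    def test_straight_line_dimension_one(self):
        s = np.zeros((256, 256), dtype=bool)
        s[128, :] = True
        assert 0.9 <= fractal_number(s) <= 1.1

    def test_filled_square_dimension_two(self):
        assert fractal_number(np.ones((256, 256), dtype=bool)) == \
            pytest.approx(2.0, abs=0.1)

    def test_dense_skeleton_exceeds_sparse(self):
        _, sparse = generate_phantom(PhantomSpec(seed=1, n_trees=2))
        _, dense = generate_phantom(PhantomSpec(seed=1, n_trees=8))
        f_sparse = fractal_number(skeletonize(sparse.mask))
        f_dense = fractal_number(skeletonize(dense.mask))
        assert f_dense > f_sparse

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fractal_number(np.zeros((64, 64), dtype=bool))


class TestQuantify:
    def test_empty_mask_zero_record(self):
        rec = quantify(np.zeros((64, 64), dtype=bool), 1.04)
        assert rec.total_length_um == 0
        assert rec.n_branch == rec.n_tail == rec.n_segments == 0
        assert math.isnan(rec.fractal_number)

    def test_unknown_pitch_rejected(self):
        with pytest.raises(ValueError, match="pixel_size"):
            quantify(np.ones((8, 8), dtype=bool), None)

    def test_straight_fibre_length_recovery(self):
        poly = np.column_stack([np.full(300, 100.0), np.arange(10.0, 310.0)])
        _, truth = render_phantom([poly], PhantomSpec(seed=0))
        rec = quantify(truth.mask, 1.04)
        assert abs(rec.total_length_um - truth.true_total_length_um) \
            / truth.true_total_length_um <= 0.05
        assert rec.n_tail == 2 and rec.n_branch == 0 and rec.n_segments == 1

    def test_phantom_count_recovery(self):
        spec = PhantomSpec(seed=24)
        _, truth = generate_phantom(spec)
        assert truth.true_n_branch >= 2  # representative branching phantom
        rec = quantify(truth.mask, spec.pixel_size_um)
        assert rec.n_branch == truth.true_n_branch
        assert rec.n_tail == truth.true_n_tail
        assert rec.n_segments == truth.true_n_segments

    def test_rot90_counts_exact_lengths_close(self):
        spec = PhantomSpec(seed=3, image_size=192)
        _, truth = generate_phantom(spec)
        r0 = quantify(truth.mask, 1.04)
        r1 = quantify(np.rot90(truth.mask), 1.04)
        assert (r0.n_branch, r0.n_tail, r0.n_segments) == \
            (r1.n_branch, r1.n_tail, r1.n_segments)
        assert r1.total_length_um == pytest.approx(r0.total_length_um, rel=0.02)

    def test_pitch_scaling(self):
        spec = PhantomSpec(seed=5, image_size=128)
        _, truth = generate_phantom(spec)
        r1 = quantify(truth.mask, 1.0)
        r2 = quantify(truth.mask, 2.0)
        assert r2.total_length_um == pytest.approx(2 * r1.total_length_um)
        assert r2.mean_segment_length_um == pytest.approx(
            2 * r1.mean_segment_length_um)
        assert (r1.n_branch, r1.n_tail, r1.n_segments) == \
            (r2.n_branch, r2.n_tail, r2.n_segments)
        assert r2.fractal_number == pytest.approx(r1.fractal_number)

    def test_mean_times_count_consistent_with_total(self):
        spec = PhantomSpec(seed=8)
        _, truth = generate_phantom(spec)
        rec = quantify(truth.mask, spec.pixel_size_um)
        slack = rec.n_branch * 2 * math.sqrt(2) * spec.pixel_size_um
        assert rec.mean_segment_length_um * rec.n_segments <= \
            rec.total_length_um + slack + 1e-6

    def test_density_convenience(self):
        poly = np.column_stack([np.full(300, 100.0), np.arange(10.0, 310.0)])
        _, truth = render_phantom([poly], PhantomSpec(seed=0))
        rec = quantify(truth.mask, 1.04)
        area_mm2 = (384 * 1.04 / 1000) ** 2
        assert rec.density_mm_per_mm2(area_mm2) == pytest.approx(
            rec.total_length_um / 1000 / area_mm2)
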