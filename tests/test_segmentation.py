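"""Segmentation: nucleus detection, seeded propagation, cytoplasm subtraction,
per-cell measurement — each checked against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage
from skimage import filters

from conftest import dijkstra_oracle
from oppscreen.segmentation import (FieldImage, LabelMap, measure_cells,
                                    propagate_cells, segment_field, segment_nuclei,
                                    subtract_nucleus)
from oppscreen.synthetic import CellSpec, FieldSpec, render_field


def _disk_image(centers, radius=6, size=96, value=1000.0, background=100.0):
    img = np.full((size, size), background)
    yy, xx = np.mgrid[0:size, 0:size]
    for (y, x) in centers:
        img[(yy - y) ** 2 + (xx - x) ** 2 <= radius ** 2] = value
    return img


class TestSegmentNuclei:
    def test_all_zero_image_empty(self):
        lm = segment_nuclei(np.zeros((32, 32)))
        assert lm.max_label == 0 and lm.kind == "nucleus"

    def test_nan_pixels_rejected(self):
        img = np.zeros((16, 16))
        img[3, 3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            segment_nuclei(img)

    def test_five_planted_disks_recovered(self):
        centers = [(20, 20), (20, 70), (48, 48), (76, 20), (76, 76)]
        lm = segment_nuclei(_disk_image(centers), min_area=20, max_area=500)
        assert lm.max_label == 5
        for (y, x) in centers:
            lab = lm.labels[y, x]
            assert lab > 0
            ys, xs = np.nonzero(lm.labels == lab)
            assert abs(ys.mean() - y) <= 1.0 and abs(xs.mean() - x) <= 1.0

    def test_bridged_disks_merge_like_connected_components(self):
        """Two disks joined by an above-threshold bridge form one component;
        oracle = scipy connected components at the same Otsu threshold."""
        img = _disk_image([(30, 20), (30, 60)], radius=6)
        img[30, 20:60] = 1000.0  # bridge
        lm = segment_nuclei(img, min_area=20, max_area=2000, sigma=0.0)
        thr = filters.threshold_otsu(img)
        oracle, n = ndimage.label(img > thr, structure=np.ones((3, 3)))
        assert n == 1 and lm.max_label == 1
        assert np.array_equal(lm.labels > 0, oracle > 0)

    def test_size_gating(self):
        img = _disk_image([(20, 20)], radius=8)   # area ~ 200
        img[40:42, 40:42] = 1000.0                # 4-px speck
        lm = segment_nuclei(img, min_area=20, max_area=2000, sigma=0.0)
        assert lm.max_label == 1
        assert lm.labels[41, 41] == 0

    def test_labels_renumbered_in_scan_order(self):
        img = _disk_image([(60, 10), (10, 60)], radius=5)
        lm = segment_nuclei(img)
        assert lm.labels[10, 60] == 1 and lm.labels[60, 10] == 2


class TestPropagateCells:
    def test_no_seeds_empty_map(self):
        lm = propagate_cells(LabelMap(np.zeros((8, 8), int), "nucleus"),
                             np.ones((8, 8)))
        assert lm.max_label == 0 and lm.kind == "cell"

    def test_negative_lambda_rejected(self):
        seeds = LabelMap(np.zeros((4, 4), int), "nucleus")
        with pytest.raises(ValueError):
            propagate_cells(seeds, np.ones((4, 4)), lambda_reg=-1.0)

    def test_max_distance_zero_keeps_nuclei(self):
        seeds = np.zeros((16, 16), int)
        seeds[4:7, 4:7] = 1
        lm = propagate_cells(LabelMap(seeds, "nucleus"), np.ones((16, 16)),
                             max_distance=0, threshold=-1.0)
        assert np.array_equal(lm.labels, seeds)

    def test_uniform_image_boundary_equidistant(self):
        """On a constant image the cost reduces to path length, so every
        pixel strictly nearer one seed takes that seed's label."""
        seeds = np.zeros((9, 21), int)
        seeds[4, 3] = 1
        seeds[4, 17] = 2
        lm = propagate_cells(LabelMap(seeds, "nucleus"), np.ones((9, 21)),
                             lambda_reg=0.05, max_distance=100, threshold=-1.0)
        for y in range(9):
            for x in range(21):
                d1 = abs(y - 4) + abs(x - 3)
                d2 = abs(y - 4) + abs(x - 17)
                if d1 < d2:
                    assert lm.labels[y, x] == 1
                elif d2 < d1:
                    assert lm.labels[y, x] == 2

    def test_step_limit_is_geodesic_bfs_distance(self):
        """With uniform intensity the labeled region is exactly the set of
        mask pixels within max_distance BFS steps of the seed."""
        seeds = np.zeros((15, 15), int)
        seeds[7, 7] = 1
        img = np.ones((15, 15))
        img[:, 10] = -5.0  # below threshold: a wall the path must respect
        lm = propagate_cells(LabelMap(seeds, "nucleus"), img, lambda_reg=0.05,
                             max_distance=5, threshold=0.0)
        mask = img > 0.0
        dist = np.full((15, 15), -1)
        dist[7, 7] = 0
        frontier = [(7, 7)]
        while frontier:
            nxt = []
            for (y, x) in frontier:
                for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ny, nx_ = y + dy, x + dx
                    if 0 <= ny < 15 and 0 <= nx_ < 15 and mask[ny, nx_] \
                            and dist[ny, nx_] < 0:
                        dist[ny, nx_] = dist[y, x] + 1
                        nxt.append((ny, nx_))
            frontier = nxt
        assert np.array_equal(lm.labels == 1, (dist >= 0) & (dist <= 5))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_shortest_path_oracle_on_random_grids(self, seed):
        """Propagation equals the exhaustive shortest-path oracle on random
        6x6 intensity grids with 2-3 seeds."""
        rng = np.random.default_rng(seed)
        img = rng.uniform(0.0, 10.0, (6, 6))
        seeds = np.zeros((6, 6), int)
        pos = rng.choice(36, size=rng.integers(2, 4), replace=False)
        for lab, p in enumerate(pos, start=1):
            seeds[divmod(p, 6)] = lab
        thr = 2.0
        lm = propagate_cells(LabelMap(seeds, "nucleus"), img, lambda_reg=0.05,
                             max_distance=10_000, threshold=thr)
        assert np.array_equal(lm.labels, dijkstra_oracle(seeds, img, 0.05, thr))

    def test_partition_invariant_to_seed_renumbering(self):
        """Permuting seed label numbers renames the partition but does not
        move any boundary (continuous random intensities: no cost ties)."""
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 10, (12, 12))
        seeds = np.zeros((12, 12), int)
        seeds[2, 2], seeds[9, 4], seeds[5, 10] = 1, 2, 3
        perm = {0: 0, 1: 3, 2: 1, 3: 2}
        seeds_p = np.vectorize(perm.get)(seeds)
        a = propagate_cells(LabelMap(seeds, "nucleus"), img, threshold=1.0,
                            max_distance=10_000).labels
        b = propagate_cells(LabelMap(seeds_p.astype(int), "nucleus"), img,
                            threshold=1.0, max_distance=10_000).labels
        assert np.array_equal(np.vectorize(perm.get)(a), b)


class TestSubtractNucleus:
    def test_cells_equal_nuclei_gives_empty_cytoplasm(self):
        lab = np.zeros((8, 8), int)
        lab[2:5, 2:5] = 1
        cyto = subtract_nucleus(LabelMap(lab, "cell"), LabelMap(lab, "nucleus"))
        assert cyto.max_label == 0 and cyto.kind == "cytoplasm"

    def test_annulus_difference_and_area_identity(self):
        yy, xx = np.mgrid[0:32, 0:32]
        d2 = (yy - 16) ** 2 + (xx - 16) ** 2
        nuc = np.where(d2 <= 25, 1, 0)
        cell = np.where(d2 <= 100, 1, 0)
        cyto = subtract_nucleus(LabelMap(cell, "cell"), LabelMap(nuc, "nucleus"))
        assert np.array_equal(cyto.labels > 0, (d2 <= 100) & (d2 > 25))
        assert cell.sum() == nuc.sum() + (cyto.labels > 0).sum()

    def test_missing_nucleus_label_rejected(self):
        cell = np.zeros((8, 8), int)
        cell[1:4, 1:4] = 2
        nuc = np.zeros((8, 8), int)
        nuc[2, 2] = 1
        with pytest.raises(ValueError, match="matching nucleus"):
            subtract_nucleus(LabelMap(cell, "cell"), LabelMap(nuc, "nucleus"))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_pixelwise_masking_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nuc = rng.integers(0, 4, (10, 10))
        cell = np.where(rng.random((10, 10)) < 0.8, nuc, 0)
        # ensure cell seeds exist for every label by construction above
        out = subtract_nucleus(LabelMap(cell, "cell"), LabelMap(nuc, "nucleus"))
        for y in range(10):
            for x in range(10):
                expected = cell[y, x] if nuc[y, x] == 0 else 0
                assert out.labels[y, x] == expected


class TestMeasureCells:
    def _maps(self):
        yy, xx = np.mgrid[0:40, 0:40]
        nuc = np.zeros((40, 40), int)
        cell = np.zeros((40, 40), int)
        for lab, (y, x) in enumerate([(12, 12), (28, 28)], start=1):
            d2 = (yy - y) ** 2 + (xx - x) ** 2
            nuc[d2 <= 16] = lab
            cell[d2 <= 64] = lab
        cyto = np.where(nuc == 0, cell, 0)
        return (LabelMap(nuc, "nucleus"), LabelMap(cell, "cell"),
                LabelMap(cyto, "cytoplasm"))

    def test_constant_image_means_equal_value(self):
        nuc, cell, cyto = self._maps()
        field = FieldImage(np.zeros((40, 40)), np.full((40, 40), 7.5))
        for r in measure_cells(field, nuc, cell, cyto):
            assert r.mean_opp_total == 7.5
            assert r.mean_opp_cytoplasm == 7.5
            assert r.cell_area == r.nucleus_area + r.cytoplasm_area

    def test_two_level_cell_recovers_planted_intensities(self):
        nuc, cell, cyto = self._maps()
        opp = np.full((40, 40), 100.0)
        opp[nuc.labels > 0] = 500.0
        opp[cyto.labels > 0] = 1200.0
        for r in measure_cells(FieldImage(np.zeros((40, 40)), opp), nuc, cell, cyto):
            assert r.mean_opp_nucleus == 500.0
            assert r.mean_opp_cytoplasm == 1200.0

    def test_weighted_mean_identity_on_random_field(self):
        nuc, cell, cyto = self._maps()
        rng = np.random.default_rng(0)
        opp = rng.uniform(0, 4000, (40, 40))
        for r in measure_cells(FieldImage(np.zeros((40, 40)), opp), nuc, cell, cyto):
            lhs = r.mean_opp_total * r.cell_area
            rhs = r.mean_opp_nucleus * r.nucleus_area + r.mean_opp_cytoplasm * r.cytoplasm_area
            assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_border_cells_flagged_not_dropped(self):
        nuc = np.zeros((20, 20), int)
        nuc[0:3, 4:7] = 1       # touches the top border once expanded
        nuc[10:13, 10:13] = 2
        cell = nuc.copy()
        cyto = np.zeros((20, 20), int)
        records = measure_cells(FieldImage(np.zeros((20, 20)), np.ones((20, 20))),
                                LabelMap(nuc, "nucleus"), LabelMap(cell, "cell"),
                                LabelMap(cyto, "cytoplasm"))
        by_id = {r.cell_id: r for r in records}
        assert by_id[1].on_border and not by_id[2].on_border
        assert by_id[1].cytoplasm_empty and np.isnan(by_id[1].mean_opp_cytoplasm)


class TestEndToEndField:
    def test_scaling_opp_channel_scales_means_not_labels(self):
        """Multiplying the OPP channel by c (with the background threshold
        and the regularizer's intensity scale adjusted accordingly) leaves
        every label map unchanged and scales every mean intensity by c."""
        cells = [CellSpec(20, 20, 4, 9, 1500.0, 900.0, 8000.0),
                 CellSpec(44, 44, 5, 11, 2200.0, 1300.0, 8000.0)]
        spec = FieldSpec(image_size=64, background=100.0, noise_sd=10.0, cells=cells)
        img, _ = render_field(spec, seed=5)
        c = 3.0
        rec1, nuc1, cell1, cyto1 = segment_field(img, threshold=500.0, lambda_reg=0.05)
        scaled = FieldImage(img.nuclei_channel, c * img.opp_channel)
        rec2, nuc2, cell2, cyto2 = segment_field(scaled, threshold=c * 500.0,
                                                 lambda_reg=0.05 * c * c)
        assert np.array_equal(cell1.labels, cell2.labels)
        assert np.array_equal(cyto1.labels, cyto2.labels)
        for a, b in zip(rec1, rec2):
            assert b.mean_opp_cytoplasm == pytest.approx(c * a.mean_opp_cytoplasm, rel=1e-12)
            assert b.mean_opp_total == pytest.approx(c * a.mean_opp_total, rel=1e-12)

    def test_segment_field_recovers_planted_cells(self):
        cells = [CellSpec(20, 20, 4, 9, 1500.0, 900.0, 8000.0),
                 CellSpec(44, 44, 5, 11, 2200.0, 1300.0, 8000.0)]
        spec = FieldSpec(image_size=64, background=100.0, noise_sd=0.0, cells=cells)
        img, _ = render_field(spec, seed=0)
        records, nuclei, _, _ = segment_field(img)
        assert nuclei.max_label == 2
        means = sorted(r.mean_opp_cytoplasm for r in records)
        assert means == pytest.approx([1500.0, 2200.0])
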