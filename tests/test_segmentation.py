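"""Thresholding, nuclei detection, cancer-cell identification, invasion counts."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from invadex import synthgen as sg
from invadex import segmentation as seg
from invadex.segmentation import (TissueImage, BinaryMask, threshold_channel,
                                  detect_nuclei, identify_cancer_cells,
                                  count_invading_cells, centroid_is_invaded,
                                  quantify_masked_intensity)


def img2d(arr, px=0.5, name="nuclei"):
    return TissueImage(channels={name: np.asarray(arr, dtype=float)},
                       pixel_size=px)


class TestThreshold:
    def test_constant_zero_channel_gives_empty_mask(self):
        m = threshold_channel(img2d(np.zeros((10, 10))), "nuclei", "otsu")
        assert not m.data.any()
        assert m.warning is not None

    def test_half_plane_fixed_threshold(self):
        arr = np.zeros((10, 10))
        arr[:, 5:] = 100.0
        m = threshold_channel(img2d(arr), "nuclei", "fixed", value=50.0)
        expected = np.zeros((10, 10), dtype=bool)
        expected[:, 5:] = True
        assert np.array_equal(m.data, expected)

    def test_fixed_requires_value(self):
        with pytest.raises(ValueError):
            threshold_channel(img2d(np.ones((4, 4))), "nuclei", "fixed")

    def test_unknown_channel_rejected(self):
        with pytest.raises(KeyError):
            threshold_channel(img2d(np.ones((4, 4))), "actin", "otsu")

    def test_mask_monotone_in_fixed_threshold(self):
        rng = np.random.default_rng(0)
        arr = rng.uniform(0, 100, (50, 50))
        im = img2d(arr)
        low = threshold_channel(im, "nuclei", "fixed", value=30.0).data
        high = threshold_channel(im, "nuclei", "fixed", value=60.0).data
        assert np.all(low[high])  # raising the cutoff never adds pixels

    def test_mask_covers_ground_truth_footprint(self):
        cfg = sg.SimulationConfig(seed=13, window=(0, 0, 200, 200),
                                  pixel_size=0.5)
        pat, _ = sg.generate_point_pattern(cfg, "hardcore", 0.002,
                                           hardcore_radius=12)
        img, gt = sg.render_tissue_image(pat, cfg, nucleus_radius=3, snr=10)
        mask = threshold_channel(img, "cytokeratin", "otsu").data
        # ground-truth footprint: discs of 2x nucleus radius at centroids
        from invadex.synthgen import _disc_mask, _um_to_px
        foot = _disc_mask(mask.shape, _um_to_px(cfg, pat.points),
                          2 * 3.0 / cfg.pixel_size)
        assert mask[foot].mean() >= 0.99


class TestDetectNuclei:
    def test_empty_mask_gives_empty_table(self):
        im = img2d(np.zeros((20, 20)))
        cells = detect_nuclei(im, BinaryMask(np.zeros((20, 20), dtype=bool),
                                             channel="nuclei"))
        assert len(cells) == 0

    def test_single_nucleus_centroid_accuracy(self):
        from invadex.spatial import PointPattern
        cfg = sg.SimulationConfig(seed=21, window=(0, 0, 100, 100),
                                  pixel_size=0.5)
        pat = PointPattern(points=np.array([(50.0, 50.0)]), region=cfg.window)
        img, _ = sg.render_tissue_image(pat, cfg, nucleus_radius=3, snr=20)
        # a single blob leaves the histogram near-unimodal, where Otsu is
        # unreliable; a fixed half-peak cutoff is the appropriate threshold
        mask = threshold_channel(img, "nuclei", "fixed", value=500.0)
        cells = detect_nuclei(img, mask, min_area=4)
        assert len(cells) == 1
        assert abs(cells.x_um[0] - 50.0) < 0.5
        assert abs(cells.y_um[0] - 50.0) < 0.5

    def test_min_area_filters_specks(self):
        arr = np.zeros((40, 40))
        arr[10:20, 10:20] = 100.0  # 10x10 px = 25 um^2 at 0.5 um/px
        arr[30, 30] = 100.0        # single pixel = 0.25 um^2
        im = img2d(arr)
        mask = BinaryMask(arr > 50, channel="nuclei")
        cells = detect_nuclei(im, mask, min_area=4, split_touching=False)
        assert len(cells) == 1

    def test_planted_nuclei_all_recovered(self):
        """Separation >= 3 radii at snr 10: every nucleus found within 1 um."""
        cfg = sg.SimulationConfig(seed=22, window=(0, 0, 300, 300),
                                  pixel_size=0.5)
        pat, gt = sg.generate_point_pattern(cfg, "hardcore", 0.002,
                                            hardcore_radius=10)
        img, _ = sg.render_tissue_image(pat, cfg, nucleus_radius=3, snr=10)
        mask = threshold_channel(img, "nuclei", "otsu")
        cells = detect_nuclei(img, mask, min_area=4)
        assert len(cells) == pat.n
        from scipy.spatial import cKDTree
        d, idx = cKDTree(np.array(gt.true_centroids)).query(cells.points)
        assert len(set(idx)) == pat.n      # bijective match
        assert d.max() < 1.0


class TestIdentifyCancerCells:
    def _cells(self, pts):
        pts = np.asarray(pts, dtype=float)
        n = len(pts)
        return seg.CellTable(cell_id=np.arange(n), x_um=pts[:, 0],
                             y_um=pts[:, 1], area_um2=np.full(n, 20.0),
                             in_cytokeratin=np.ones(n, dtype=bool))

    def test_all_inside_mask_unchanged(self):
        cells = self._cells([(5, 5), (10, 10)])
        mask = BinaryMask(np.ones((40, 40), dtype=bool))
        out = identify_cancer_cells(cells, mask, pixel_size=0.5)
        assert len(out) == 2

    def test_empty_mask_empties_table(self):
        cells = self._cells([(5, 5), (10, 10)])
        mask = BinaryMask(np.zeros((40, 40), dtype=bool))
        out = identify_cancer_cells(cells, mask, pixel_size=0.5)
        assert len(out) == 0

    def test_stromal_nuclei_outside_cytokeratin_removed(self):
        """150 tumor + 50 stromal planted nuclei: exactly 150 retained."""
        cfg = sg.SimulationConfig(seed=23, window=(0, 0, 400, 400),
                                  pixel_size=0.5)
        # tumor cells in the left half, stroma safely to the right
        rng = np.random.default_rng(23)
        tumor = np.column_stack([rng.uniform(20, 180, 150),
                                 rng.uniform(20, 380, 150)])
        stroma = np.column_stack([rng.uniform(240, 380, 50),
                                  rng.uniform(20, 380, 50)])
        from invadex.spatial import PointPattern
        img, gt = sg.render_mixed_tissue_image(
            PointPattern(points=tumor, region=cfg.window), stroma, cfg,
            nucleus_radius=3, snr=20)
        ck = threshold_channel(img, "cytokeratin", "otsu")
        cells = self._cells(np.vstack([tumor, stroma]))
        out = identify_cancer_cells(cells, ck, pixel_size=cfg.pixel_size)
        assert len(out) == 150


class TestInvasionCount:
    def test_planted_invaders_counted(self):
        cfg = sg.SimulationConfig(seed=24, window=(0, 0, 400, 400),
                                  pixel_size=1.0)
        z, gt = sg.generate_invasion_field(cfg, n_central=60, n_invaded=15)
        n = count_invading_cells(z, gt.extra["central_polygon"])
        assert n == 15

    def test_no_cells_outside_gives_zero(self):
        cfg = sg.SimulationConfig(seed=25, window=(0, 0, 400, 400),
                                  pixel_size=1.0)
        z, gt = sg.generate_invasion_field(cfg, n_central=40, n_invaded=0)
        assert count_invading_cells(z, gt.extra["central_polygon"]) == 0

    def test_boundary_centroid_counts_as_invaded(self):
        square = Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])
        assert centroid_is_invaded((10.0, 5.0), square) is True   # on edge
        assert centroid_is_invaded((5.0, 5.0), square) is False   # interior
        assert centroid_is_invaded((15.0, 5.0), square) is True   # outside

    def test_degenerate_polygon_rejected(self):
        cfg = sg.SimulationConfig(seed=26, window=(0, 0, 200, 200),
                                  pixel_size=1.0)
        z, _ = sg.generate_invasion_field(cfg, n_central=10, n_invaded=0,
                                          central_radius_frac=0.4)
        with pytest.raises(ValueError):
            count_invading_cells(z, [(0, 0), (10, 0), (20, 0)])

    def test_invariant_to_z_order_permutation(self):
        cfg = sg.SimulationConfig(seed=27, window=(0, 0, 300, 300),
                                  pixel_size=1.0)
        z, gt = sg.generate_invasion_field(cfg, n_central=30, n_invaded=8)
        n1 = count_invading_cells(z, gt.extra["central_polygon"])
        shuffled = TissueImage(
            channels={"nuclei": z.channel("nuclei")[::-1].copy()},
            pixel_size=z.pixel_size, z_step=z.z_step)
        assert count_invading_cells(shuffled, gt.extra["central_polygon"]) == n1


class TestMaskedIntensity:
    def test_uniform_signal(self):
        im = img2d(np.full((20, 20), 7.0), name="signal")
        mask = BinaryMask(np.zeros((20, 20), dtype=bool))
        mask.data[3:8, 3:8] = True
        assert quantify_masked_intensity(im, "signal", mask) == 7.0

    def test_signal_equals_mask(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5:10, 5:10] = True
        im = img2d(m.astype(float), name="signal")
        assert quantify_masked_intensity(im, "signal", BinaryMask(m)) == 1.0

    def test_empty_mask_is_error(self):
        im = img2d(np.ones((10, 10)), name="signal")
        with pytest.raises(ValueError):
            quantify_masked_intensity(im, "signal", BinaryMask(np.zeros((10, 10), dtype=bool)))

    def test_planted_enrichment_recovered(self):
        rng = np.random.default_rng(28)
        m = np.zeros((100, 100), dtype=bool)
        m[20:60, 20:60] = True
        signal = np.where(m, 200.0, 100.0) + rng.normal(0, 2.0, (100, 100))
        im = img2d(signal, name="signal")
        inside = quantify_masked_intensity(im, "signal", BinaryMask(m))
        outside = quantify_masked_intensity(im, "signal", BinaryMask(~m))
        assert inside / outside == pytest.approx(2.0, rel=0.02)
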