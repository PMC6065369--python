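"""Generators: seed determinism, intensity conservation, ground truth."""

import numpy as np
import pytest

from invadex import synthgen as sg
from invadex import meta2x2


def cfg(seed=0, window=(0, 0, 100, 100), px=0.5):
    return sg.SimulationConfig(seed=seed, window=window, pixel_size=px)


class TestConfig:
    def test_rejects_empty_window(self):
        with pytest.raises(ValueError):
            sg.SimulationConfig(window=(0, 0, 0, 100))

    def test_rejects_nonpositive_pixel_size(self):
        with pytest.raises(ValueError):
            sg.SimulationConfig(pixel_size=0)


class TestPointPattern:
    def test_seed_determinism(self):
        c = cfg(seed=5, window=(0, 0, 10, 10))
        p1, _ = sg.generate_point_pattern(c, "poisson", 0.04)
        p2, _ = sg.generate_point_pattern(c, "poisson", 0.04)
        assert np.array_equal(p1.points, p2.points)

    @pytest.mark.parametrize("process,kwargs", [
        ("poisson", {}),
        ("thomas_cluster", {"cluster_params": (0.001, 5.0, 10.0)}),
        ("hardcore", {"hardcore_radius": 3.0}),
    ])
    def test_points_inside_window_and_ground_truth_complete(self, process, kwargs):
        c = cfg(seed=1, window=(10, 20, 210, 170))
        pat, gt = sg.generate_point_pattern(c, process, 0.01, **kwargs)
        assert pat.n == len(gt.true_centroids) == len(gt.true_labels)
        assert pat.n == gt.true_counts["n_points"]
        x0, y0, x1, y1 = c.window
        if pat.n:
            assert pat.points[:, 0].min() >= x0 and pat.points[:, 0].max() < x1
            assert pat.points[:, 1].min() >= y0 and pat.points[:, 1].max() < y1

    def test_poisson_mean_count(self):
        """Realized counts average to lambda * area (Monte-Carlo, 100 seeds)."""
        counts = [
            sg.generate_point_pattern(cfg(seed=s, window=(0, 0, 1000, 1000)),
                                      "poisson", 0.01)[0].n
            for s in range(100)
        ]
        assert abs(np.mean(counts) - 10_000) / 10_000 < 0.01

    def test_thomas_realized_intensity(self):
        """Neyman-Scott identity: realized intensity = kappa * mu_off."""
        counts = [
            sg.generate_point_pattern(
                cfg(seed=s, window=(0, 0, 500, 500)), "thomas_cluster", 0.04,
                cluster_params=(0.001, 5.0, 40.0))[0].n
            for s in range(100)
        ]
        area = 500.0 * 500.0
        mean, se = np.mean(counts), np.std(counts, ddof=1) / 10.0
        assert abs(mean - 0.04 * area) < 3 * se

    def test_hardcore_respects_minimum_distance(self):
        pat, _ = sg.generate_point_pattern(cfg(seed=3, window=(0, 0, 200, 200)),
                                           "hardcore", 0.002, hardcore_radius=10)
        from scipy.spatial.distance import pdist
        assert pdist(pat.points).min() >= 10.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sg.generate_point_pattern(cfg(), "poisson", -1.0)
        with pytest.raises(ValueError, match="inconsistent"):
            sg.generate_point_pattern(cfg(), "thomas_cluster", 0.04,
                                      cluster_params=(0.001, 5.0, 10.0))
        with pytest.raises(ValueError):
            sg.generate_point_pattern(cfg(), "banana", 0.01)


class TestRenderTissueImage:
    def test_empty_pattern_is_noise_only(self):
        from invadex.spatial import PointPattern
        c = cfg(seed=2)
        img, gt = sg.render_tissue_image(
            PointPattern(points=np.empty((0, 2)), region=c.window), c, snr=5)
        # after nucleus-scale smoothing (the detection filter), pure noise
        # stays far below the blob peak
        from scipy.ndimage import gaussian_filter
        smoothed = gaussian_filter(img.channel("nuclei"), sigma=3.0)
        assert smoothed.max() < 0.5 * 1000.0
        assert gt.true_counts["n_cells"] == 0

    def test_single_centroid_peak_position(self):
        from invadex.spatial import PointPattern
        c = cfg(seed=2, window=(0, 0, 100, 100), px=0.5)
        pat = PointPattern(points=np.array([(50.0, 50.0)]), region=c.window)
        img, _ = sg.render_tissue_image(pat, c, nucleus_radius=3, snr=50)
        i, j = np.unravel_index(np.argmax(img.channel("nuclei")),
                                img.channel("nuclei").shape)
        # (50, 50) um -> pixel center between indices 99 and 100
        assert abs(i - 99.5) <= 1 and abs(j - 99.5) <= 1

    @pytest.mark.parametrize("snr,tol_px", [
        (1e6, 1.0),   # noiseless render: blob peak sits at the centroid pixel
        (10.0, 2.0),  # at snr 10 the argmax jitters by up to ~1 px extra
    ])
    def test_every_centroid_has_local_max(self, snr, tol_px):
        c = cfg(seed=4, window=(0, 0, 300, 300))
        pat, gt = sg.generate_point_pattern(c, "hardcore", 0.002,
                                            hardcore_radius=12)
        img, _ = sg.render_tissue_image(pat, c, nucleus_radius=3, snr=snr)
        from scipy.ndimage import gaussian_filter
        from skimage.feature import peak_local_max
        # matched smoothing at the nucleus scale before peak detection
        smoothed = gaussian_filter(img.channel("nuclei"), sigma=2.0)
        peaks = peak_local_max(smoothed, min_distance=3,
                               threshold_abs=200.0, exclude_border=False)
        from scipy.spatial import cKDTree
        tree = cKDTree(peaks)
        assert len(peaks) == pat.n
        x0, y0, x1, y1 = c.window
        for x, y in gt.true_centroids:
            # border-clipped blobs have their rendered maximum shifted
            # inward; the peak-position property applies to whole blobs
            if min(x - x0, x1 - x, y - y0, y1 - y) < 3.0:
                continue
            d, _ = tree.query([y / c.pixel_size - 0.5, x / c.pixel_size - 0.5])
            assert d <= tol_px

    def test_unresolvable_radius_rejected(self):
        from invadex.spatial import PointPattern
        c = cfg(px=2.0)
        pat = PointPattern(points=np.array([(50.0, 50.0)]), region=c.window)
        with pytest.raises(ValueError, match="resolvability"):
            sg.render_tissue_image(pat, c, nucleus_radius=3.0)


class TestKymographGenerator:
    def test_zero_ruffles_uniform_background(self):
        kymo, gt = sg.generate_kymograph(cfg(seed=1), n_ruffles=0, snr=1e9)
        assert np.ptp(kymo.raster) < 1e-3
        assert gt.true_counts["n_ruffles"] == 0

    def test_traces_recorded_with_planted_speed(self):
        _, gt = sg.generate_kymograph(cfg(seed=2), n_ruffles=3, speed=2.0)
        assert len(gt.true_ruffle_traces) == 3
        assert all(tr[2] == 2.0 for tr in gt.true_ruffle_traces)

    def test_seed_determinism(self):
        k1, _ = sg.generate_kymograph(cfg(seed=9), n_ruffles=2, speed=1.0)
        k2, _ = sg.generate_kymograph(cfg(seed=9), n_ruffles=2, speed=1.0)
        assert np.array_equal(k1.raster, k2.raster)


class TestOtherGenerators:
    def test_contingency_null_geometric_mean_or(self):
        """At true OR = 1, the geometric mean sample OR over 1000 seeds is
        within 5% of 1 (log-OR is the unbiased null scale; the arithmetic
        mean carries the OR estimator's upward small-sample skew)."""
        log_ors = []
        for s in range(1000):
            t, _ = sg.generate_contingency(cfg(seed=s), 50, 50, 0.3, 1.0)
            o, _ = meta2x2.odds_ratio(t)
            log_ors.append(np.log(o))
        assert abs(np.exp(np.mean(log_ors)) - 1.0) < 0.05

    def test_contingency_margins_and_ground_truth(self):
        t, gt = sg.generate_contingency(cfg(seed=3), 40, 60, 0.25, 2.0)
        assert t.a + t.b == 40 and t.c + t.d == 60
        assert gt.true_or == 2.0

    def test_contingency_invalid_parameters(self):
        with pytest.raises(ValueError):
            sg.generate_contingency(cfg(), 10, 10, 1.5, 1.0)
        with pytest.raises(ValueError):
            sg.generate_contingency(cfg(), -1, 10, 0.3, 1.0)

    def test_dcis_zero_structures(self):
        c = cfg(seed=5, window=(0, 0, 200, 200), px=1.0)
        _, gt = sg.generate_dcis_section(c, n_structures=0,
                                         cellular_fraction=0.5)
        assert gt.true_counts["n_structures"] == 0

    def test_dcis_invalid_fraction(self):
        with pytest.raises(ValueError):
            sg.generate_dcis_section(cfg(), cellular_fraction=1.5)

    def test_expression_planted_hit_bookkeeping(self):
        expr, gt = sg.generate_expression(cfg(seed=6), n_genes=1000,
                                          n_samples_per_group=5,
                                          planted_fc=4.0,
                                          planted_fraction=0.05)
        assert len(gt.true_de_genes) == 50
        assert expr.values.shape == (1000, 10)
        assert set(gt.true_de_genes) <= set(expr.values.index)

    def test_zseries_band_ground_truth_masks_consistent(self):
        c = cfg(seed=7, window=(0, 0, 30, 30), px=0.2)
        img, gt = sg.generate_zseries_with_band(c, band_width=3, enrichment=2,
                                                cell_radius=10)
        band, cell = gt.extra["band_mask"], gt.extra["cell_mask"]
        assert band.sum() > 0 and np.all(cell[band])
        assert img.channel("actin").shape[0] == 5  # z-slices

    def test_invasion_field_counts(self):
        c = cfg(seed=8, window=(0, 0, 400, 400), px=1.0)
        _, gt = sg.generate_invasion_field(c, n_central=30, n_invaded=10)
        assert gt.true_counts == {"n_central": 30, "n_invaded": 10}
        assert len(gt.true_centroids) == 40
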