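"""End-to-end recovery checks against synthetic ground truth.

Each routine regenerates its inputs from a seed, runs the relevant part of
the pipeline, and returns the measured recovery statistics.  The oracles
used here (all-pairs nearest-neighbor search, exhaustive hypergeometric
enumeration) are deliberately independent of the implementations they
check.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

from . import synthgen as sg
from . import segmentation as seg
from . import dynamics
from . import dcis as dcis_mod
from . import meta2x2
from .spatial import PointPattern, analyze_pattern, compute_nnd, classify_lii, _welch

__all__ = [
    "check_nnd_oracle", "check_poisson_closed_form",
    "check_clustering_monotonicity", "check_segmentation_recovery",
    "check_fisher_oracle", "check_ci_coverage", "check_kymograph_recovery",
    "check_band_geometry", "check_cohort_discrimination", "check_dcis",
]


def brute_force_nnd(points: np.ndarray) -> np.ndarray:
    """All-pairs O(n^2) nearest-neighbor distances (the oracle)."""
    points = np.asarray(points, dtype=float)
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    return np.sqrt(d2.min(axis=1))


def fisher_enumeration_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration over the margins."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    ks = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ks, n, col1, row1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    return float(min(pmf[pmf <= p_obs * (1 + 1e-12)].sum(), 1.0))


def check_nnd_oracle(seed: int = 0, n_patterns: int = 100,
                     max_n: int = 2000) -> dict:
    """Accelerated NND vs the brute-force oracle on random patterns."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    total = 0
    for _ in range(n_patterns):
        n = int(rng.integers(2, max_n + 1))
        pts = rng.uniform(0, 500, (n, 2))
        recs = compute_nnd(PointPattern(points=pts, region=(0, 0, 500, 500)))
        oracle = brute_force_nnd(pts)
        got = np.array([r.nnd for r in recs])
        mismatches += int((got != oracle).sum())
        total += n
    return {"mismatches": mismatches, "points_checked": total}


def check_poisson_closed_form(seed: int = 0, n_reps: int = 200,
                              intensities=(0.005, 0.01, 0.04, 0.1),
                              window=(0.0, 0.0, 500.0, 500.0)) -> dict:
    """Edge-excluded mean LII vs the Poisson closed form 1/(2 sqrt(lambda))."""
    rows = []
    for i, lam in enumerate(intensities):
        liis = []
        for r in range(n_reps):
            cfg = sg.SimulationConfig(seed=seed + 7919 * r + 13 * i,
                                      window=window)
            pat, _ = sg.generate_point_pattern(cfg, "poisson", lam)
            liis.append(analyze_pattern(pat).lii)
        expected = 1.0 / (2.0 * np.sqrt(lam))
        mean = float(np.mean(liis))
        rows.append({
            "intensity": lam, "mean_lii": mean, "expected": expected,
            "rel_dev": abs(mean - expected) / expected,
            "se": float(np.std(liis, ddof=1) / np.sqrt(n_reps)),
        })
    return {"per_intensity": rows,
            "max_rel_dev": max(r["rel_dev"] for r in rows),
            "n_reps": n_reps}


def check_clustering_monotonicity(seed: int = 0, n_reps: int = 100,
                                  intensity: float = 0.01,
                                  window=(0.0, 0.0, 200.0, 200.0)) -> dict:
    """Mean LII ordering at matched intensity: Thomas < Poisson < hardcore."""
    mu_off, sigma = 20.0, 5.0
    means = {}
    for proc, kwargs in [
        ("thomas_cluster", {"cluster_params": (intensity / mu_off, sigma, mu_off)}),
        ("poisson", {}),
        ("hardcore", {}),
    ]:
        liis = []
        for r in range(n_reps):
            cfg = sg.SimulationConfig(seed=seed + 104729 * r + len(proc),
                                      window=window)
            pat, _ = sg.generate_point_pattern(cfg, proc, intensity, **kwargs)
            liis.append(analyze_pattern(pat).lii)
        means[proc] = float(np.mean(liis))
    return {"means": means, "n_reps": n_reps,
            "ordering_ok": means["thomas_cluster"] < means["poisson"]
            < means["hardcore"]}


def check_segmentation_recovery(seed: int = 0, n_images: int = 8,
                                snr: float = 5.0,
                                nucleus_radius: float = 3.0) -> dict:
    """Planted-count recovery, centroid RMSE, and LII agreement.

    Hardcore patterns enforce nucleus separation of at least three radii;
    the pipeline is render -> threshold -> detect -> cytokeratin gate ->
    LII, compared per image against the ground-truth centroids.
    """
    from scipy.spatial import cKDTree
    count_errors = 0
    sq_err_px = []
    lii_rel_devs = []
    n_cells = 0
    for k in range(n_images):
        cfg = sg.SimulationConfig(seed=seed + 613 * k,
                                  window=(0, 0, 300, 300), pixel_size=0.5)
        pat, gt = sg.generate_point_pattern(
            cfg, "hardcore", 0.002, hardcore_radius=3.4 * nucleus_radius)
        img, _ = sg.render_tissue_image(pat, cfg,
                                        nucleus_radius=nucleus_radius, snr=snr)
        nuc_mask = seg.threshold_channel(img, "nuclei", "otsu",
                                         smooth_sigma_um=nucleus_radius / 2)
        cells = seg.detect_nuclei(img, nuc_mask, min_area=4.0)
        ck_mask = seg.threshold_channel(img, "cytokeratin", "otsu",
                                        smooth_sigma_um=1.0)
        cancer = seg.identify_cancer_cells(cells, ck_mask, cfg.pixel_size)
        count_errors += abs(len(cancer) - pat.n)
        n_cells += pat.n
        d, _ = cKDTree(np.asarray(gt.true_centroids)).query(cancer.points)
        sq_err_px.extend((d / cfg.pixel_size) ** 2)
        lii_seg = analyze_pattern(
            PointPattern(points=cancer.points, region=cfg.window)).lii
        lii_true = analyze_pattern(pat).lii
        lii_rel_devs.append(abs(lii_seg - lii_true) / lii_true)
    return {
        "count_error_total": count_errors,
        "centroid_rmse_px": float(np.sqrt(np.mean(sq_err_px))),
        "lii_max_rel_dev": float(max(lii_rel_devs)),
        "n_cells": n_cells, "n_images": n_images,
    }


def check_fisher_oracle(seed: int = 0, n_tables: int = 1000,
                        max_n: int = 40) -> dict:
    """Two-sided Fisher p vs exhaustive enumeration, plus the worked table."""
    rng = np.random.default_rng(seed)
    max_dev = 0.0
    for _ in range(n_tables):
        n = int(rng.integers(4, max_n + 1))
        cut = np.sort(rng.choice(np.arange(1, n), size=3, replace=False))
        a, b = int(cut[0]), int(cut[1] - cut[0])
        c, d = int(cut[2] - cut[1]), int(n - cut[2])
        p = meta2x2.fisher_exact_p(
            meta2x2.ContingencyTable2x2("t", a, b, c, d))
        max_dev = max(max_dev, abs(p - fisher_enumeration_p(a, b, c, d)))
    worked = meta2x2.fisher_exact_p(meta2x2.ContingencyTable2x2("w", 3, 0, 0, 3))
    worked_oracle = fisher_enumeration_p(3, 0, 0, 3)
    return {"max_abs_dev": max_dev, "worked_table_p": worked,
            "worked_table_p_oracle": worked_oracle, "n_tables": n_tables}


def check_ci_coverage(seed: int = 0, n_tables: int = 1000,
                      true_ors=(1.0, 3.0), n_per_arm: int = 50,
                      baseline_risk: float = 0.3) -> dict:
    """Coverage of the 95% conditional exact CI at planted odds ratios."""
    coverage = {}
    for i, tor in enumerate(true_ors):
        cover = 0
        for s in range(n_tables):
            t, _ = sg.generate_contingency(
                sg.SimulationConfig(seed=seed + 31 * i + 2 * s + 1),
                n_per_arm, n_per_arm, baseline_risk, tor)
            lo, hi = meta2x2.exact_ci(t)
            cover += lo <= tor <= hi
        coverage[tor] = cover / n_tables
    return {"coverage": coverage, "n_tables": n_tables}


def check_kymograph_recovery(seed: int = 0, n_kymographs: int = 50) -> dict:
    """Planted trace counts and speeds recovered from rendered kymographs."""
    rng = np.random.default_rng(seed)
    count_errors = 0
    max_speed_rel_err = 0.0
    for k in range(n_kymographs):
        speed = float(rng.uniform(0.5, 5.0))
        n_ruffles = int(rng.integers(1, 5))
        kymo, gt = sg.generate_kymograph(
            sg.SimulationConfig(seed=seed + 389 * k + 11),
            n_ruffles=n_ruffles, speed=speed)
        rs = dynamics.detect_ruffles(kymo)
        count_errors += abs(rs.count - n_ruffles)
        for s in rs.speeds:
            max_speed_rel_err = max(max_speed_rel_err,
                                    abs(s - speed) / speed)
    return {"count_error_total": count_errors,
            "max_speed_rel_err": max_speed_rel_err,
            "n_kymographs": n_kymographs}


def check_band_geometry(seed: int = 0) -> dict:
    """Annulus geometry and planted enrichment of the leading-edge band.

    A disc cell of radius 10 um with a 3 um band has band/cell area ratio
    (10^2 - 7^2) / 10^2 = 0.51.
    """
    cfg = sg.SimulationConfig(seed=seed + 5, window=(0, 0, 30, 30),
                              pixel_size=0.2)
    z, _ = sg.generate_zseries_with_band(cfg, band_width=3.0, enrichment=2.0,
                                         cell_radius=10.0)
    band = dynamics.leading_edge_band(z, width_um=3.0)
    cell = seg.threshold_channel(z, "actin", "otsu").data
    ratio = float(band.data.sum() / cell.sum())
    enrich = dynamics.band_enrichment_ratio(z, band, cell, "marker")
    return {"area_ratio": ratio, "expected_area_ratio": 0.51,
            "enrichment_ratio": float(enrich), "expected_enrichment": 2.0}


def check_cohort_discrimination(seed: int = 0, n_per_group: int = 40) -> dict:
    """Full pipeline separates cohesive (clustered) from dispersed tumors.

    Cohesive tumors are Thomas-cluster patterns (tight multicellular nests,
    expected LII bin "low"); dispersed tumors are hardcore patterns at a
    density chosen so the expected LII bin is "high".  Each tumor is
    rendered, segmented, and scored; agreement is the fraction of tumors
    whose LII bin matches the ground-truth class.
    """
    lii_cohesive, lii_dispersed = [], []
    agree = 0
    for k in range(n_per_group):
        cfg = sg.SimulationConfig(seed=seed + 211 * k + 1,
                                  window=(0, 0, 300, 300), pixel_size=0.5)
        pat, _ = sg.generate_point_pattern(
            cfg, "thomas_cluster", 0.004,
            cluster_params=(0.004 / 15.0, 6.0, 15.0))
        lii = _segment_and_score(pat, cfg)
        lii_cohesive.append(lii)
        agree += classify_lii(lii) == "low"
    for k in range(n_per_group):
        cfg = sg.SimulationConfig(seed=seed + 431 * k + 2,
                                  window=(0, 0, 300, 300), pixel_size=0.5)
        pat, _ = sg.generate_point_pattern(cfg, "hardcore", 0.0025,
                                           hardcore_radius=6.0)
        lii = _segment_and_score(pat, cfg)
        lii_dispersed.append(lii)
        agree += classify_lii(lii) == "high"
    t, p = _welch(np.asarray(lii_dispersed), np.asarray(lii_cohesive))
    return {
        "agreement": agree / (2 * n_per_group),
        "welch_t": t, "welch_p": p,
        "direction_ok": bool(np.mean(lii_dispersed) > np.mean(lii_cohesive)),
        "mean_lii_cohesive": float(np.mean(lii_cohesive)),
        "mean_lii_dispersed": float(np.mean(lii_dispersed)),
        "n_tumors": 2 * n_per_group,
    }


def _segment_and_score(pat, cfg, nucleus_radius: float = 1.5,
                       snr: float = 10.0) -> float:
    img, _ = sg.render_tissue_image(pat, cfg, nucleus_radius=nucleus_radius,
                                    snr=snr)
    nuc_mask = seg.threshold_channel(img, "nuclei", "otsu",
                                     smooth_sigma_um=nucleus_radius / 2)
    cells = seg.detect_nuclei(img, nuc_mask, min_area=1.0,
                              min_separation_um=2.0 * nucleus_radius)
    ck_mask = seg.threshold_channel(img, "cytokeratin", "otsu",
                                    smooth_sigma_um=1.0)
    cancer = seg.identify_cancer_cells(cells, ck_mask, cfg.pixel_size)
    return analyze_pattern(
        PointPattern(points=cancer.points, region=cfg.window)).lii


def check_dcis(seed: int = 0, n_sections: int = 4) -> dict:
    """DCIS arithmetic and synthetic-section recovery."""
    worked = dcis_mod.dcis_index(
        dcis_mod.DCISSection(n_structures=10, tumor_area=2.0,
                             cellular_area=1.0)).dcis_index
    count_errors = 0
    max_fraction_dev = 0.0
    fractions = (0.3, 0.45, 0.6, 0.8, 0.5, 0.7)
    for k in range(n_sections):
        frac = fractions[k % len(fractions)]
        n_structures = 6 + 2 * k
        cfg = sg.SimulationConfig(seed=seed + 97 * k + 3,
                                  window=(0, 0, 500, 500), pixel_size=1.0)
        img, _ = sg.generate_dcis_section(cfg, n_structures=n_structures,
                                          cellular_fraction=frac)
        sec = dcis_mod.measure_section(img)
        count_errors += abs(sec.n_structures - n_structures)
        coeff = dcis_mod.cellular_coefficient(sec)
        max_fraction_dev = max(max_fraction_dev, abs(coeff - frac) / frac)
    return {"worked_index": worked, "expected_worked_index": 2.5,
            "structure_count_error_total": count_errors,
            "max_fraction_rel_dev": max_fraction_dev,
            "n_sections": n_sections}
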