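"""Synthetic ground-truth data generators.

Every input the invasion-analysis pipeline consumes — tumor-cell point
patterns, rendered cytokeratin/nuclei tissue images, confocal z-series,
kymographs, DCIS sections, per-study 2x2 contingency tables and grouped
expression matrices — can be generated here with the planted ground truth
recorded alongside, so that every downstream measurement can be validated
against known quantities.

Coordinate convention: continuous micrometre coordinates with the origin at
the window corner and y increasing downward (raster convention).  Pixel
(i, j) of a rendered image has its center at ((j + 0.5) * px, (i + 0.5) * px).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .segmentation import TissueImage
from .spatial import PointPattern
from .meta2x2 import ContingencyTable2x2
from .dynamics import Kymograph

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_point_pattern",
    "render_tissue_image",
    "generate_kymograph",
    "generate_zseries_with_band",
    "generate_invasion_field",
    "generate_dcis_section",
    "generate_contingency",
    "generate_expression",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Reproducibility envelope for every generator.

    Parameters
    ----------
    seed : int
        Seed for numpy's PCG64 generator; identical seed plus parameters
        gives bit-identical output.
    window : tuple of float
        Analysis window (x0, y0, x1, y1) in micrometres; must have
        positive area.
    pixel_size : float
        Micrometres per pixel for rendered rasters; must be positive.
    """

    seed: int = 0
    window: tuple[float, float, float, float] = (0.0, 0.0, 500.0, 500.0)
    pixel_size: float = 0.5

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.window
        if not (x1 > x0 and y1 > y0):
            raise ValueError("window must have positive area")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.window
        return (x1 - x0) * (y1 - y0)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def raster_shape(self) -> tuple[int, int]:
        x0, y0, x1, y1 = self.window
        ny = int(round((y1 - y0) / self.pixel_size))
        nx = int(round((x1 - x0) / self.pixel_size))
        return ny, nx


@dataclass
class GroundTruth:
    """Planted quantities for a single generated object.

    Each generator fills only the fields relevant to it; every rendered
    object has exactly one ground-truth record.
    """

    true_centroids: list[tuple[float, float]] = field(default_factory=list)
    true_labels: list[str] = field(default_factory=list)
    true_ruffle_traces: list[tuple[float, float, float]] = field(default_factory=list)
    true_counts: dict[str, int] = field(default_factory=dict)
    true_or: float | None = None
    true_de_genes: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# point patterns
# ---------------------------------------------------------------------------

def generate_point_pattern(
    config: SimulationConfig,
    process: str = "poisson",
    intensity: float = 0.01,
    cluster_params: tuple[float, float, float] | None = None,
    hardcore_radius: float | None = None,
) -> tuple[PointPattern, GroundTruth]:
    """Simulate a planar point process inside the config window.

    Parameters
    ----------
    process : {'poisson', 'thomas_cluster', 'hardcore'}
        Homogeneous Poisson, Thomas (Neyman-Scott) cluster process, or a
        dart-throwing hardcore (minimum-distance) process.
    intensity : float
        Target intensity lambda in cells / um^2.
    cluster_params : (kappa, sigma, mu_off), required for 'thomas_cluster'
        Parent intensity (parents/um^2), Gaussian offspring displacement
        s.d. (um), and mean offspring per parent.  Must satisfy
        kappa * mu_off == intensity to 1e-9.
    hardcore_radius : float, for 'hardcore'
        Minimum allowed inter-point distance in um (default: half the
        mean Poisson nearest-neighbor spacing).

    Returns
    -------
    (PointPattern, GroundTruth)
    """
    if not intensity > 0:
        raise ValueError("intensity must be positive")
    rng = config.rng()
    x0, y0, x1, y1 = config.window
    w, h = x1 - x0, y1 - y0

    if process == "poisson":
        n = rng.poisson(intensity * config.area)
        pts = np.column_stack([
            x0 + rng.uniform(0, w, n),
            y0 + rng.uniform(0, h, n),
        ])
    elif process == "thomas_cluster":
        if cluster_params is None:
            raise ValueError("thomas_cluster requires cluster_params=(kappa, sigma, mu_off)")
        kappa, sigma, mu_off = cluster_params
        if kappa <= 0 or sigma <= 0 or mu_off <= 0:
            raise ValueError("cluster parameters must be positive")
        if abs(kappa * mu_off - intensity) > 1e-9:
            raise ValueError(
                f"cluster params inconsistent with intensity: kappa*mu_off="
                f"{kappa * mu_off!r} != {intensity!r}"
            )
        # plus-sampling: simulate parents in a window enlarged by 4 sigma on
        # all sides so offspring intensity has no edge deficit
        m = 4.0 * sigma
        ext_area = (w + 2 * m) * (h + 2 * m)
        n_par = rng.poisson(kappa * ext_area)
        px = x0 - m + rng.uniform(0, w + 2 * m, n_par)
        py = y0 - m + rng.uniform(0, h + 2 * m, n_par)
        n_off = rng.poisson(mu_off, n_par)
        cx = np.repeat(px, n_off) + rng.normal(0, sigma, int(n_off.sum()))
        cy = np.repeat(py, n_off) + rng.normal(0, sigma, int(n_off.sum()))
        keep = (cx >= x0) & (cx < x1) & (cy >= y0) & (cy < y1)
        pts = np.column_stack([cx[keep], cy[keep]])
    elif process == "hardcore":
        if hardcore_radius is None:
            hardcore_radius = 0.25 / math.sqrt(intensity)
        if hardcore_radius <= 0:
            raise ValueError("hardcore_radius must be positive")
        target = rng.poisson(intensity * config.area)
        buf = np.empty((target, 2))
        n_acc = 0
        r2 = hardcore_radius ** 2
        max_tries = 200 * max(target, 1)
        tries = 0
        while n_acc < target and tries < max_tries:
            tries += 1
            cand = np.array([x0 + rng.uniform(0, w), y0 + rng.uniform(0, h)])
            if n_acc == 0 or np.min(
                    ((buf[:n_acc] - cand) ** 2).sum(axis=1)) >= r2:
                buf[n_acc] = cand
                n_acc += 1
        pts = buf[:n_acc].copy()
    else:
        raise ValueError(f"unknown process {process!r}")

    pattern = PointPattern(points=pts, region=config.window)
    gt = GroundTruth(
        true_centroids=[tuple(p) for p in pts],
        true_labels=["cell"] * len(pts),
        true_counts={"n_points": len(pts)},
        extra={"process": process, "intensity": intensity},
    )
    return pattern, gt


# ---------------------------------------------------------------------------
# rendered tissue images
# ---------------------------------------------------------------------------

def _render_gaussian_blobs(shape, centers_px, sigma_px, amplitude=1.0):
    """Sum of isotropic Gaussian blobs on a pixel grid (vectorized per blob)."""
    img = np.zeros(shape, dtype=float)
    ny, nx = shape
    r = int(math.ceil(4 * sigma_px))
    for ci, cj in centers_px:
        i0, i1 = max(0, int(ci) - r), min(ny, int(ci) + r + 1)
        j0, j1 = max(0, int(cj) - r), min(nx, int(cj) + r + 1)
        if i0 >= i1 or j0 >= j1:
            continue
        ii = np.arange(i0, i1)[:, None]
        jj = np.arange(j0, j1)[None, :]
        img[i0:i1, j0:j1] += amplitude * np.exp(
            -((ii - ci) ** 2 + (jj - cj) ** 2) / (2 * sigma_px ** 2)
        )
    return img


def _um_to_px(config: SimulationConfig, pts: np.ndarray) -> np.ndarray:
    """Continuous (x, y) um -> continuous (row, col) px, pixel-center aligned."""
    x0, y0, _, _ = config.window
    col = (pts[:, 0] - x0) / config.pixel_size - 0.5
    row = (pts[:, 1] - y0) / config.pixel_size - 0.5
    return np.column_stack([row, col])


def _disc_mask(shape, centers_px, radius_px):
    mask = np.zeros(shape, dtype=bool)
    ny, nx = shape
    r = int(math.ceil(radius_px)) + 1
    for ci, cj in centers_px:
        i0, i1 = max(0, int(ci) - r), min(ny, int(ci) + r + 1)
        j0, j1 = max(0, int(cj) - r), min(nx, int(cj) + r + 1)
        if i0 >= i1 or j0 >= j1:
            continue
        ii = np.arange(i0, i1)[:, None]
        jj = np.arange(j0, j1)[None, :]
        mask[i0:i1, j0:j1] |= (ii - ci) ** 2 + (jj - cj) ** 2 <= radius_px ** 2
    return mask


def render_tissue_image(
    pattern: PointPattern,
    config: SimulationConfig,
    nucleus_radius: float = 3.0,
    snr: float = 10.0,
    peak: float = 1000.0,
) -> tuple[TissueImage, GroundTruth]:
    """Render a two-channel (nuclei, cytokeratin) immunofluorescence image.

    Nuclei are Gaussian blobs (s.d. = nucleus_radius / 2) at the pattern's
    centroids; the cytokeratin channel is the dilated union of per-cell
    footprints (discs of 2x the nucleus radius).  Additive Gaussian noise
    with sigma = peak / snr is applied to both channels.
    """
    if nucleus_radius < 2 * config.pixel_size:
        raise ValueError("nucleus_radius below resolvability (< 2 pixels)")
    if not snr > 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(config.seed + 1)
    shape = config.raster_shape()
    pts = np.asarray(pattern.points, dtype=float).reshape(-1, 2)
    centers_px = _um_to_px(config, pts) if len(pts) else np.empty((0, 2))

    sigma_px = (nucleus_radius / 2.0) / config.pixel_size
    nuclei = _render_gaussian_blobs(shape, centers_px, sigma_px, amplitude=peak)
    ck = np.where(
        _disc_mask(shape, centers_px, 2.0 * nucleus_radius / config.pixel_size),
        peak, 0.0,
    )
    noise_sd = peak / snr
    nuclei = nuclei + rng.normal(0, noise_sd, shape)
    ck = ck + rng.normal(0, noise_sd, shape)

    img = TissueImage(
        channels={"nuclei": nuclei, "cytokeratin": ck},
        pixel_size=config.pixel_size,
    )
    gt = GroundTruth(
        true_centroids=[tuple(p) for p in pts],
        true_labels=["cell"] * len(pts),
        true_counts={"n_cells": len(pts)},
        extra={"nucleus_radius": nucleus_radius, "snr": snr, "peak": peak},
    )
    return img, gt


def render_mixed_tissue_image(
    tumor_pattern: PointPattern,
    stromal_points: np.ndarray,
    config: SimulationConfig,
    nucleus_radius: float = 3.0,
    snr: float = 10.0,
    peak: float = 1000.0,
) -> tuple[TissueImage, GroundTruth]:
    """Render tumor + stromal nuclei where only tumor cells carry cytokeratin.

    Stromal nuclei appear in the nuclei channel but lie outside the
    cytokeratin footprint, emulating the tumor/stroma discrimination the
    cytokeratin mask performs on real sections.
    """
    if nucleus_radius < 2 * config.pixel_size:
        raise ValueError("nucleus_radius below resolvability (< 2 pixels)")
    rng = np.random.default_rng(config.seed + 1)
    shape = config.raster_shape()
    tum = np.asarray(tumor_pattern.points, dtype=float).reshape(-1, 2)
    stro = np.asarray(stromal_points, dtype=float).reshape(-1, 2)
    all_pts = np.vstack([tum, stro]) if len(stro) else tum
    centers_px = _um_to_px(config, all_pts) if len(all_pts) else np.empty((0, 2))
    tum_px = _um_to_px(config, tum) if len(tum) else np.empty((0, 2))

    sigma_px = (nucleus_radius / 2.0) / config.pixel_size
    nuclei = _render_gaussian_blobs(shape, centers_px, sigma_px, amplitude=peak)
    ck = np.where(
        _disc_mask(shape, tum_px, 2.0 * nucleus_radius / config.pixel_size),
        peak, 0.0,
    )
    noise_sd = peak / snr
    nuclei = nuclei + rng.normal(0, noise_sd, shape)
    ck = ck + rng.normal(0, noise_sd, shape)
    img = TissueImage(channels={"nuclei": nuclei, "cytokeratin": ck},
                      pixel_size=config.pixel_size)
    gt = GroundTruth(
        true_centroids=[tuple(p) for p in all_pts],
        true_labels=["tumor"] * len(tum) + ["stromal"] * len(stro),
        true_counts={"n_tumor": len(tum), "n_stromal": len(stro)},
        extra={"nucleus_radius": nucleus_radius, "snr": snr, "peak": peak},
    )
    return img, gt


# ---------------------------------------------------------------------------
# kymographs
# ---------------------------------------------------------------------------

def generate_kymograph(
    config: SimulationConfig,
    n_ruffles: int = 3,
    speed: float = 2.0,
    duration: float = 10.0,
    extent: float = 20.0,
    space_scale: float = 0.2,
    time_scale: float = 5.0,
    snr: float = 10.0,
    peak: float = 1000.0,
) -> tuple[Kymograph, GroundTruth]:
    """Render a space x time kymograph with planted linear ruffle traces.

    Each ruffle is a bright line of slope `speed` (um/min) in physical
    units: rows are space (um), columns are time (frames).  Traces are
    staggered in time so they never cross; (start_x, start_t, speed) of
    every trace is recorded in the GroundTruth.
    """
    if n_ruffles < 0:
        raise ValueError("n_ruffles must be >= 0")
    if speed < 0:
        raise ValueError("speed must be >= 0")
    rng = config.rng()
    n_space = max(4, int(round(extent / space_scale)))
    n_time = max(4, int(round(duration * 60.0 / time_scale)))
    raster = np.zeros((n_space, n_time), dtype=float)
    traces: list[tuple[float, float, float]] = []

    # Parallel traces x(t) = c + v t never cross; their raster separation is
    # the spacing of the intercepts c, so slots in intercept space with
    # within-slot jitter guarantee distinct, non-touching streaks.
    c_lo = -0.6 * speed * duration
    c_hi = 0.75 * extent
    for k in range(n_ruffles):
        slot = (c_hi - c_lo) / max(n_ruffles, 1)
        c = c_lo + (k + 0.25 + 0.5 * rng.uniform()) * slot
        if speed > 0 and c < 0:
            x_start, t_start = 0.0, -c / speed
        else:
            x_start, t_start = max(c, 0.0), 0.0
        traces.append((x_start, t_start, speed))
        t_min = np.arange(n_time) * time_scale / 60.0
        x_um = c + speed * t_min
        valid = (x_um >= 0) & (x_um < extent)
        cols = np.nonzero(valid)[0]
        rows = x_um[valid] / space_scale
        for col, r in zip(cols, rows):
            i = int(round(r))
            for di in (-1, 0, 1):  # 3-px-wide trace
                if 0 <= i + di < n_space:
                    raster[i + di, col] += peak * math.exp(-(di ** 2) / 2.0)

    raster += rng.normal(0, peak / snr, raster.shape)
    kymo = Kymograph(raster=raster, space_scale=space_scale, time_scale=time_scale)
    gt = GroundTruth(
        true_ruffle_traces=traces,
        true_counts={"n_ruffles": n_ruffles},
        extra={"speed": speed, "extent": extent, "duration": duration},
    )
    return kymo, gt


# ---------------------------------------------------------------------------
# z-series generators
# ---------------------------------------------------------------------------

def generate_zseries_with_band(
    config: SimulationConfig,
    band_width: float = 3.0,
    enrichment: float = 2.0,
    cell_radius: float = 10.0,
    n_slices: int = 5,
    z_step: float = 0.2,
    snr: float = 50.0,
    peak: float = 1000.0,
) -> tuple[TissueImage, GroundTruth]:
    """Confocal z-series of one disc-shaped cell with a membrane-proximal band.

    The actin channel is a filled disc (the cell) per slice; the marker
    channel has base intensity inside the cell, multiplied by `enrichment`
    within `band_width` um of the cell edge — the planted analog of
    leading-edge accumulation of pMLC / Arp2/3.
    """
    if band_width <= 0 or enrichment <= 0 or cell_radius <= 0:
        raise ValueError("band_width, enrichment and cell_radius must be positive")
    rng = config.rng()
    shape = config.raster_shape()
    x0, y0, x1, y1 = config.window
    cx_um, cy_um = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    ii = (np.arange(shape[0])[:, None] + 0.5) * config.pixel_size + y0
    jj = (np.arange(shape[1])[None, :] + 0.5) * config.pixel_size + x0
    rho = np.sqrt((jj - cx_um) ** 2 + (ii - cy_um) ** 2)
    cell = rho <= cell_radius
    band = cell & (rho >= cell_radius - band_width)

    base = 0.5 * peak
    actin = np.where(cell, peak, 0.0)
    marker = np.where(cell, base, 0.0)
    marker[band] = base * enrichment

    noise_sd = peak / snr
    actin3 = np.stack([actin + rng.normal(0, noise_sd, shape) for _ in range(n_slices)])
    marker3 = np.stack([marker + rng.normal(0, noise_sd, shape) for _ in range(n_slices)])
    img = TissueImage(
        channels={"actin": actin3, "marker": marker3},
        pixel_size=config.pixel_size, z_step=z_step,
    )
    gt = GroundTruth(
        true_centroids=[(cx_um, cy_um)],
        true_counts={"n_cells": 1},
        extra={
            "cell_radius": cell_radius, "band_width": band_width,
            "enrichment": enrichment, "base_intensity": base,
            "band_mask": band, "cell_mask": cell,
        },
    )
    return img, gt


def generate_invasion_field(
    config: SimulationConfig,
    n_central: int = 200,
    n_invaded: int = 50,
    central_radius_frac: float = 0.3,
    n_slices: int = 3,
    z_step: float = 1.5,
    nucleus_radius: float = 4.0,
    snr: float = 10.0,
    peak: float = 1000.0,
) -> tuple[TissueImage, GroundTruth]:
    """3D-culture invasion field: nuclei z-series with a central spheroid region.

    `n_central` nuclei are placed inside a central disc (the original cell
    mass) and `n_invaded` outside it (cells that invaded into the
    surrounding matrix).  The central polygon is recorded in the
    GroundTruth so counting can be validated exactly.
    """
    if n_central < 0 or n_invaded < 0:
        raise ValueError("counts must be >= 0")
    rng = config.rng()
    x0, y0, x1, y1 = config.window
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    r_c = central_radius_frac * min(x1 - x0, y1 - y0) / 2.0

    def _sample(n, inside: bool, min_sep: float,
                existing: list[tuple[float, float]]):
        out: list[tuple[float, float]] = []
        tries = 0
        while len(out) < n and tries < 20000 * max(n, 1):
            tries += 1
            px_, py_ = rng.uniform(x0, x1), rng.uniform(y0, y1)
            d = math.hypot(px_ - cx, py_ - cy)
            margin = 2.0 * nucleus_radius
            if inside and d > r_c - margin:
                continue
            if not inside and d < r_c + margin:
                continue
            if all(math.hypot(px_ - q[0], py_ - q[1]) >= min_sep
                   for q in existing + out):
                out.append((px_, py_))
        if len(out) < n:
            raise ValueError("window too small for requested counts at this separation")
        return out

    # central cells may crowd (the cell mass is dense; merged blobs still lie
    # inside the region); invaded cells must stay individually countable
    central = _sample(n_central, True, 1.0 * nucleus_radius, [])
    invaded = _sample(n_invaded, False, 3.0 * nucleus_radius, central)
    pts = np.asarray(central + invaded, dtype=float).reshape(-1, 2)
    shape = config.raster_shape()
    centers_px = _um_to_px(config, pts) if len(pts) else np.empty((0, 2))
    sigma_px = (nucleus_radius / 2.0) / config.pixel_size
    base = _render_gaussian_blobs(shape, centers_px, sigma_px, amplitude=peak)
    slices = []
    for _ in range(n_slices):
        slices.append(base + rng.normal(0, peak / snr, shape))
    img = TissueImage(channels={"nuclei": np.stack(slices)},
                      pixel_size=config.pixel_size, z_step=z_step)
    theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    poly = [(cx + r_c * math.cos(t), cy + r_c * math.sin(t)) for t in theta]
    gt = GroundTruth(
        true_centroids=[tuple(p) for p in pts],
        true_labels=["central"] * n_central + ["invaded"] * n_invaded,
        true_counts={"n_central": n_central, "n_invaded": n_invaded},
        extra={"central_polygon": poly, "central_radius": r_c},
    )
    return img, gt


# ---------------------------------------------------------------------------
# DCIS sections
# ---------------------------------------------------------------------------

def generate_dcis_section(
    config: SimulationConfig,
    n_structures: int = 10,
    cellular_fraction: float = 0.5,
    structure_radius: float = 12.0,
    snr: float = 50.0,
    peak: float = 1000.0,
) -> tuple[TissueImage, GroundTruth]:
    """Synthetic tumor mid-section for DCIS-index validation.

    The section is a disc-shaped tumor region ("tissue" channel).  The
    "cells" channel marks cellular (non-stromal) area covering exactly
    `cellular_fraction` of the tumor pixels at moderate intensity, plus
    `n_structures` bright ring-shaped intact structures at full intensity.
    """
    if not 0.0 <= cellular_fraction <= 1.0:
        raise ValueError("cellular_fraction must be in [0, 1]")
    if n_structures < 0:
        raise ValueError("n_structures must be >= 0")
    rng = config.rng()
    shape = config.raster_shape()
    x0, y0, x1, y1 = config.window
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    R = 0.45 * min(x1 - x0, y1 - y0)
    ii = (np.arange(shape[0])[:, None] + 0.5) * config.pixel_size + y0
    jj = (np.arange(shape[1])[None, :] + 0.5) * config.pixel_size + x0
    rho = np.sqrt((jj - cx) ** 2 + (ii - cy) ** 2)
    tumor = rho <= R

    # cellular mask: smoothed noise field thresholded at the quantile that
    # yields exactly the requested within-tumor pixel fraction
    from scipy.ndimage import gaussian_filter
    fieldv = gaussian_filter(rng.normal(size=shape), sigma=10.0 / config.pixel_size)
    vals = fieldv[tumor]
    if cellular_fraction >= 1.0:
        cellular = tumor.copy()
    elif cellular_fraction <= 0.0:
        cellular = np.zeros_like(tumor)
    else:
        thr = np.quantile(vals, 1.0 - cellular_fraction)
        cellular = tumor & (fieldv >= thr)

    # non-overlapping rings inside the tumor disc
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_structures and tries < 50000:
        tries += 1
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, max(R - 1.8 * structure_radius, 0.0))
        c = (cx + rad * math.cos(ang), cy + rad * math.sin(ang))
        if all(math.hypot(c[0] - q[0], c[1] - q[1]) >= 3.0 * structure_radius
               for q in centers):
            centers.append(c)
    if len(centers) < n_structures:
        raise ValueError("window too small for requested number of structures")
    rings = np.zeros(shape, dtype=bool)
    for sx, sy in centers:
        rr = np.sqrt((jj - sx) ** 2 + (ii - sy) ** 2)
        rings |= (rr <= structure_radius) & (rr >= structure_radius * 0.6)

    tissue_ch = np.where(tumor, 0.3 * peak, 0.0)
    cells_ch = np.where(cellular, 0.5 * peak, 0.0)
    cells_ch[rings] = peak
    noise_sd = peak / snr
    tissue_ch = tissue_ch + rng.normal(0, noise_sd, shape)
    cells_ch = cells_ch + rng.normal(0, noise_sd, shape)

    img = TissueImage(channels={"tissue": tissue_ch, "cells": cells_ch},
                      pixel_size=config.pixel_size)
    gt = GroundTruth(
        true_centroids=centers,
        true_counts={"n_structures": n_structures},
        extra={
            "cellular_fraction": cellular_fraction,
            "tumor_radius": R,
            "structure_radius": structure_radius,
            "tumor_mask": tumor,
            "cellular_mask": cellular | rings,
        },
    )
    return img, gt


# ---------------------------------------------------------------------------
# contingency tables and expression matrices
# ---------------------------------------------------------------------------

def generate_contingency(
    config: SimulationConfig,
    n_exposed: int = 50,
    n_unexposed: int = 50,
    baseline_risk: float = 0.3,
    true_or: float = 1.0,
    study_id: str = "synthetic",
) -> tuple[ContingencyTable2x2, GroundTruth]:
    """Sample one study's 2x2 exposure x outcome table at a planted odds ratio.

    Unexposed outcome probability is `baseline_risk`; the exposed
    probability is derived by scaling the baseline odds by `true_or`.
    """
    if n_exposed < 0 or n_unexposed < 0:
        raise ValueError("group sizes must be >= 0")
    if not 0.0 < baseline_risk < 1.0:
        raise ValueError("baseline_risk must be in (0, 1)")
    if not true_or > 0:
        raise ValueError("true_or must be positive")
    rng = config.rng()
    odds0 = baseline_risk / (1.0 - baseline_risk)
    odds1 = true_or * odds0
    p1 = odds1 / (1.0 + odds1)
    a = int(rng.binomial(n_exposed, p1))
    c = int(rng.binomial(n_unexposed, baseline_risk))
    table = ContingencyTable2x2(study_id=study_id, a=a, b=n_exposed - a,
                                c=c, d=n_unexposed - c)
    gt = GroundTruth(true_or=true_or,
                     extra={"p_exposed": p1, "p_unexposed": baseline_risk})
    return table, gt


def generate_expression(
    config: SimulationConfig,
    n_genes: int = 1000,
    n_samples_per_group: int = 20,
    planted_fc: float = 4.0,
    planted_fraction: float = 0.05,
    sigma_log2: float = 0.5,
    group_names: tuple[str, str] = ("ERpos", "ERneg"),
):
    """Grouped log-normal expression matrix with a planted hit set.

    Intensities are log-normal; the first round(n_genes * planted_fraction)
    genes carry a multiplicative fold change of `planted_fc` in the first
    group.  Returns (ExpressionMatrix, GroundTruth); the planted hit gene
    ids are recorded exactly.
    """
    from .gene_screen import ExpressionMatrix
    import pandas as pd

    if n_genes <= 0 or n_samples_per_group <= 0:
        raise ValueError("n_genes and n_samples_per_group must be positive")
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must be in [0, 1]")
    if planted_fc <= 0:
        raise ValueError("planted_fc must be positive")
    rng = config.rng()
    n_hits = int(round(n_genes * planted_fraction))
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    base_log2 = rng.uniform(4, 10, n_genes)
    n = n_samples_per_group
    log2_a = base_log2[:, None] + rng.normal(0, sigma_log2, (n_genes, n))
    log2_b = base_log2[:, None] + rng.normal(0, sigma_log2, (n_genes, n))
    log2_a[:n_hits, :] += math.log2(planted_fc)
    values = np.hstack([2.0 ** log2_a, 2.0 ** log2_b])
    samples = [f"{group_names[0]}_{i}" for i in range(n)] + \
              [f"{group_names[1]}_{i}" for i in range(n)]
    groups = [group_names[0]] * n + [group_names[1]] * n
    df = pd.DataFrame(values, index=genes, columns=samples)
    expr = ExpressionMatrix(values=df, groups=pd.Series(groups, index=samples),
                            gene_list=genes)
    gt = GroundTruth(true_de_genes=genes[:n_hits],
                     extra={"planted_fc": planted_fc, "n_hits": n_hits})
    return expr, gt
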