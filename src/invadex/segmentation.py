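"""Cancer-cell detection from cytokeratin / nuclei immunofluorescence.

Cancer cells are identified by cytokeratin positivity: a binary mask is
generated by thresholding the cytokeratin channel, nuclei are segmented
from the nuclei channel, and only nuclei whose centroid falls inside the
cytokeratin mask are retained as cancer cells.  The same machinery counts
invading cells in 3D-culture z-series (maximum-intensity projection,
threshold, component count outside the central region) and quantifies
mask-restricted mean protein intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, Polygon
from skimage.filters import threshold_otsu
from skimage.feature import peak_local_max
from skimage.measure import label, regionprops
from skimage.segmentation import watershed

__all__ = [
    "TissueImage",
    "BinaryMask",
    "CellTable",
    "threshold_channel",
    "detect_nuclei",
    "identify_cancer_cells",
    "count_invading_cells",
    "quantify_masked_intensity",
]


@dataclass
class TissueImage:
    """Multi-channel 2D or 3D intensity raster with physical pixel size.

    channels maps channel name (e.g. "cytokeratin", "nuclei", "actin") to a
    2D (y, x) or 3D (z, y, x) float array; all channels share one shape.
    pixel_size is um/px in-plane; z_step is um between slices for 3D data.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    z_step: float | None = None

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"unknown channel {name!r}; have {sorted(self.channels)}")
        return self.channels[name]

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape


@dataclass
class BinaryMask:
    """Boolean raster aligned to a TissueImage channel, with provenance."""

    data: np.ndarray
    channel: str = ""
    method: str = ""
    value: float | None = None
    warning: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)


@dataclass
class CellTable:
    """Per-cell table: id, centroid (um), area (um^2), cytokeratin flag."""

    cell_id: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    x_um: np.ndarray = field(default_factory=lambda: np.array([]))
    y_um: np.ndarray = field(default_factory=lambda: np.array([]))
    area_um2: np.ndarray = field(default_factory=lambda: np.array([]))
    in_cytokeratin: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    def __len__(self) -> int:
        return len(self.cell_id)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x_um, self.y_um]) if len(self) else \
            np.empty((0, 2))

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "cell_id": self.cell_id, "x_um": self.x_um, "y_um": self.y_um,
            "area_um2": self.area_um2, "in_ck": self.in_cytokeratin,
        })

    @classmethod
    def from_dataframe(cls, df) -> "CellTable":
        return cls(
            cell_id=df["cell_id"].to_numpy(dtype=int),
            x_um=df["x_um"].to_numpy(dtype=float),
            y_um=df["y_um"].to_numpy(dtype=float),
            area_um2=df.get("area_um2", 0.0 * df["x_um"]).to_numpy(dtype=float),
            in_cytokeratin=df.get("in_ck", df["x_um"] == df["x_um"]).to_numpy(dtype=bool),
        )


def threshold_channel(img: TissueImage, channel: str, method: str = "otsu",
                      value: float | None = None,
                      smooth_sigma_um: float = 0.0) -> BinaryMask:
    """Binary mask of one channel by Otsu's method or a fixed cutoff.

    `smooth_sigma_um` applies a Gaussian matched filter before
    thresholding; at low snr the raw histogram is near-unimodal and Otsu
    lands inside the noise, while object-scale smoothing restores the
    bimodality it needs.  A constant channel under Otsu yields an all-zero
    mask with a warning flag rather than an error.
    """
    data = img.channel(channel)
    if smooth_sigma_um > 0:
        data = ndimage.gaussian_filter(
            data.astype(float), sigma=smooth_sigma_um / img.pixel_size)
    if method == "fixed":
        if value is None:
            raise ValueError("fixed threshold requires a value")
        thr = float(value)
        warning = None
    elif method == "otsu":
        if np.ptp(data) == 0:
            return BinaryMask(np.zeros_like(data, dtype=bool), channel=channel,
                              method="otsu", value=None,
                              warning="constant channel; empty mask")
        thr = float(threshold_otsu(data))
        warning = None
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    method_tag = method if smooth_sigma_um == 0 else \
        f"{method}+smooth{smooth_sigma_um}um"
    return BinaryMask(data >= thr, channel=channel, method=method_tag,
                      value=thr, warning=warning)


def detect_nuclei(img: TissueImage, mask_nuclei: BinaryMask,
                  min_area: float = 4.0,
                  split_touching: bool = True,
                  min_separation_um: float | None = None) -> CellTable:
    """Segment nuclei from a binary nuclei mask.

    Connected components with area >= min_area (um^2) are kept; touching
    nuclei are split by local-maximum marker seeding on the intensity image
    followed by watershed.  Centroids are intensity-weighted and returned
    in um (pixel-center convention).  An empty mask yields an empty table.
    """
    if not min_area > 0:
        raise ValueError("min_area must be positive")
    mask = mask_nuclei.data
    if mask.ndim != 2:
        raise ValueError("detect_nuclei operates on 2D masks")
    intensity = img.channel(mask_nuclei.channel) if mask_nuclei.channel in \
        img.channels else img.channel("nuclei")
    px = img.pixel_size
    if not mask.any():
        return CellTable()

    if split_touching:
        min_dist_px = max(2, int(round((min_separation_um or 3.0) / px)))
        smoothed = ndimage.gaussian_filter(intensity.astype(float), sigma=1.0)
        coords = peak_local_max(smoothed, min_distance=min_dist_px,
                                labels=mask, exclude_border=False)
        markers = np.zeros(mask.shape, dtype=int)
        for k, (i, j) in enumerate(coords, start=1):
            markers[i, j] = k
        if markers.max() == 0:
            labels = label(mask)
        else:
            labels = watershed(-smoothed, markers=markers, mask=mask)
    else:
        labels = label(mask)

    rows = []
    for prop in regionprops(labels, intensity_image=intensity):
        area_um2 = prop.area * px * px
        if area_um2 < min_area:
            continue
        ci, cj = prop.centroid_weighted if np.any(
            np.asarray(prop.image_intensity) > 0) else prop.centroid
        rows.append(((cj + 0.5) * px, (ci + 0.5) * px, area_um2))
    if not rows:
        return CellTable()
    xs, ys, areas = map(np.asarray, zip(*rows))
    n = len(xs)
    return CellTable(cell_id=np.arange(n), x_um=xs, y_um=ys, area_um2=areas,
                     in_cytokeratin=np.ones(n, dtype=bool))


def identify_cancer_cells(cells: CellTable, ck_mask: BinaryMask,
                          pixel_size: float) -> CellTable:
    """Retain only nuclei whose centroid pixel lies inside the cytokeratin mask."""
    if len(cells) == 0:
        return cells
    mask = ck_mask.data
    ii = np.clip((cells.y_um / pixel_size - 0.5).round().astype(int), 0,
                 mask.shape[0] - 1)
    jj = np.clip((cells.x_um / pixel_size - 0.5).round().astype(int), 0,
                 mask.shape[1] - 1)
    inside = mask[ii, jj]
    return CellTable(
        cell_id=np.arange(int(inside.sum())),
        x_um=cells.x_um[inside], y_um=cells.y_um[inside],
        area_um2=cells.area_um2[inside],
        in_cytokeratin=np.ones(int(inside.sum()), dtype=bool),
    )


def centroid_is_invaded(xy: tuple[float, float], central_region: Polygon) -> bool:
    """Invaded iff the centroid lies outside the open interior of the central
    region; points exactly on the boundary count as invaded."""
    return not central_region.contains(Point(*xy))


def count_invading_cells(zseries: TissueImage,
                         central_region: Polygon | list[tuple[float, float]],
                         nuclei_channel: str = "nuclei",
                         min_area: float = 4.0,
                         smooth_sigma_um: float = 2.0) -> int:
    """Count cells that left the central region of a 3D invasion culture.

    The nuclei z-series is maximum-intensity projected, smoothed at the
    nucleus scale (matched filter; without it, sparse fields leave the
    histogram unimodal and automatic thresholding unstable), thresholded
    (Otsu), and labeled; components whose centroid falls outside the
    central region are counted as invaded.  Centroids exactly on the
    polygon boundary count as invaded (the exclusion zone is the region's
    interior).
    """
    poly = central_region if isinstance(central_region, Polygon) else \
        Polygon(central_region)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("degenerate central region polygon")
    stack = zseries.channel(nuclei_channel)
    mip = stack.max(axis=0) if stack.ndim == 3 else stack
    if smooth_sigma_um > 0:
        mip = ndimage.gaussian_filter(
            mip, sigma=smooth_sigma_um / zseries.pixel_size)
    proj = TissueImage(channels={nuclei_channel: mip},
                       pixel_size=zseries.pixel_size)
    mask = threshold_channel(proj, nuclei_channel, method="otsu")
    cells = detect_nuclei(proj, BinaryMask(mask.data, channel=nuclei_channel),
                          min_area=min_area)
    return sum(centroid_is_invaded((x, y), poly) for x, y in cells.points)


def quantify_masked_intensity(img: TissueImage, signal_channel: str,
                              mask: BinaryMask) -> float:
    """Arithmetic mean of a signal channel over the mask pixels/voxels."""
    m = mask.data
    sig = img.channel(signal_channel)
    if m.shape != sig.shape:
        raise ValueError("mask shape does not match channel shape")
    if not m.any():
        raise ValueError("empty mask: mean intensity undefined")
    return float(sig[m].mean())
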