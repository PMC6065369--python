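"""DCIS index: cellularity-corrected abundance of intact tumor structures.

For a tumor mid-section, intact non-disseminated DCIS structures are
counted; the cellular coefficient is the fraction of the tumor area that is
cellular (excluding stroma); and the DCIS index is

    index = n_structures * cellular_coefficient / tumor_area

i.e. structures per unit tumor area, corrected for cellularity.  A high
index means the tumor retains many intact in-situ structures relative to
its size — the histologic signature of low dissemination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label, regionprops
from skimage.morphology import convex_hull_image

from .segmentation import TissueImage, threshold_channel

__all__ = ["DCISSection", "DCISResult", "cellular_coefficient", "dcis_index",
           "measure_section"]


@dataclass
class DCISSection:
    """Measured quantities for one section; areas in the declared unit^2."""

    n_structures: int
    tumor_area: float
    cellular_area: float
    unit: str = "mm"

    def __post_init__(self) -> None:
        if self.tumor_area <= 0:
            raise ValueError("tumor_area must be positive")
        if not 0 <= self.cellular_area <= self.tumor_area:
            raise ValueError("cellular_area must lie in [0, tumor_area]")
        if self.n_structures < 0:
            raise ValueError("n_structures must be >= 0")


@dataclass
class DCISResult:
    cellular_coefficient: float
    dcis_index: float
    unit: str = "mm"  # index has units structures / unit^2


def cellular_coefficient(section: DCISSection) -> float:
    """Cellular area divided by total tumor area (dimensionless, in [0, 1])."""
    return section.cellular_area / section.tumor_area


def dcis_index(section: DCISSection) -> DCISResult:
    """Structure count times cellular coefficient, normalized by tumor area."""
    coeff = cellular_coefficient(section)
    return DCISResult(
        cellular_coefficient=coeff,
        dcis_index=section.n_structures * coeff / section.tumor_area,
        unit=section.unit,
    )


def measure_section(
    img: TissueImage,
    tissue_channel: str = "tissue",
    cells_channel: str = "cells",
    structure_threshold_frac: float = 0.75,
    min_structure_area_um2: float = 50.0,
    n_structures_override: int | None = None,
    unit: str = "mm",
) -> DCISSection:
    """Measure tumor area, cellular area and structure count from a section image.

    Tumor area is the convex hull of the thresholded tissue mask; cellular
    area is the Otsu-thresholded cells mask; intact structures are counted
    as connected components of the cells channel above
    `structure_threshold_frac` of its maximum (structures are rendered or
    stained much brighter than diffuse cellular regions).  On real H&E
    material structure identification is a manual call, so a manual count
    can be supplied via `n_structures_override`.

    Areas are returned in `unit`^2 (default mm).
    """
    tissue = img.channel(tissue_channel)
    if np.ptp(tissue) == 0:
        raise ValueError("blank section image")
    tissue_mask = threshold_channel(img, tissue_channel, method="otsu").data
    if not tissue_mask.any():
        raise ValueError("no tissue detected")
    hull = convex_hull_image(tissue_mask)

    cells_mask = threshold_channel(img, cells_channel, method="otsu").data
    cells_mask &= hull

    px = img.pixel_size  # um
    scale = {"um": 1.0, "mm": 1e-3}[unit] ** 2  # um^2 -> unit^2 is (scale)
    px_area = (px * px) * scale

    if n_structures_override is not None:
        n_structures = int(n_structures_override)
    else:
        cells = img.channel(cells_channel)
        thr = cells.min() + structure_threshold_frac * np.ptp(cells)
        struct_mask = cells >= thr
        struct_mask = ndimage.binary_closing(struct_mask, iterations=2)
        labels = label(struct_mask)
        n_structures = sum(
            1 for p in regionprops(labels)
            if p.area * px * px >= min_structure_area_um2
        )

    return DCISSection(
        n_structures=n_structures,
        tumor_area=float(hull.sum()) * px_area,
        cellular_area=float(cells_mask.sum()) * px_area,
        unit=unit,
    )
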