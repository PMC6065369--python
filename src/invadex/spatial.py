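"""Nearest-neighbor distances and the Local Invasion Index (LII).

The LII treats cancer-cell nuclei in a tumor section as a planar point
pattern: each cell's nearest-neighbor distance (NND) is the Euclidean
distance to its most proximal neighboring cell, and the tumor-level LII is
the mean NND over cells that survive border correction.  Cells are excluded
when their NND zone — the closed disc centered at the cell with radius equal
to its NND — is not fully contained in the analysis region, which removes
the censoring bias of cells near the region border whose true nearest
neighbor may lie outside the imaged area.

Higher LII means cells are more scattered, i.e. more locally invasive.
Tumors are binned as "low" (LII <= 7 um) or "high" (LII >= 9 um) by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy import stats
from shapely.geometry import Point, Polygon

__all__ = [
    "PointPattern",
    "NNDRecord",
    "LIIResult",
    "PopulationSummary",
    "compute_nnd",
    "apply_edge_exclusion",
    "compute_lii",
    "classify_lii",
    "analyze_pattern",
    "population_analysis",
    "compare_lii_groups",
]

# relative slack for tangency ("closed containment"): a disc exactly tangent
# to the border counts as contained despite floating-point boundary distances
_TANGENT_RTOL = 1e-9


@dataclass
class PointPattern:
    """Cell centroids (um) inside an analysis region.

    region is either a rectangle (x0, y0, x1, y1) or a shapely Polygon
    (TMA cores are circular, so polygonal regions are first-class).
    """

    points: np.ndarray
    region: tuple[float, float, float, float] | Polygon

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    @property
    def n(self) -> int:
        return len(self.points)

    def region_polygon(self) -> Polygon:
        if isinstance(self.region, Polygon):
            return self.region
        x0, y0, x1, y1 = self.region
        return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])

    def boundary_distance(self, pts: np.ndarray) -> np.ndarray:
        """Distance from each point to the region boundary (vectorized for
        rectangles, shapely for polygons)."""
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        if isinstance(self.region, Polygon):
            ext = self.region.exterior
            return np.array([ext.distance(Point(p)) for p in pts])
        x0, y0, x1, y1 = self.region
        return np.minimum.reduce([
            pts[:, 0] - x0, x1 - pts[:, 0],
            pts[:, 1] - y0, y1 - pts[:, 1],
        ])


@dataclass
class NNDRecord:
    cell_id: int
    nnd: float
    neighbor_id: int
    included: bool = True


@dataclass
class LIIResult:
    lii: float
    n_total: int
    n_included: int
    bin: str
    per_cell: list[NNDRecord] = field(default_factory=list)


@dataclass
class PopulationSummary:
    """Per-group summary of a per-cell NND population."""

    n: int
    mean: float
    median: float
    above_median: np.ndarray
    below_median: np.ndarray
    bin_edges: np.ndarray
    histogram_counts: np.ndarray
    histogram_percent: np.ndarray


def compute_nnd(pattern: PointPattern) -> list[NNDRecord]:
    """Euclidean nearest-neighbor distance for every point.

    Uses a k-d tree but is contractually identical to the O(n^2) all-pairs
    computation; ties in distance are broken by the lowest neighbor id.
    Duplicate points (distance zero) are rejected: identical centroids
    indicate an upstream segmentation fault.
    """
    pts = pattern.points
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 points to compute nearest neighbors")
    tree = cKDTree(pts)
    k = min(n, 3)
    dist, idx = tree.query(pts, k=k)
    nnd = dist[:, 1]
    nbr = idx[:, 1].astype(int)
    if np.any(nnd == 0.0):
        raise ValueError("duplicate points (zero nearest-neighbor distance)")
    # a tie is possible only when the 3rd neighbor is exactly as close as
    # the 2nd; resolve those by lowest neighbor id
    maybe_tied = np.zeros(n, dtype=bool) if k < 3 else dist[:, 2] == nnd
    records = []
    for i in range(n):
        d = nnd[i]
        j = int(nbr[i])
        if maybe_tied[i]:
            cand = tree.query_ball_point(pts[i], d * (1 + 1e-12))
            ties = [m for m in cand if m != i
                    and float(np.sqrt(((pts[m] - pts[i]) ** 2).sum())) == d]
            if ties:
                j = min(ties)
        records.append(NNDRecord(cell_id=i, nnd=float(d), neighbor_id=j))
    return records


def apply_edge_exclusion(records: list[NNDRecord],
                         pattern: PointPattern) -> list[NNDRecord]:
    """Flag cells whose NND zone is not fully contained in the region.

    A cell is included iff the closed disc of radius nnd centered at the
    cell lies entirely within the analysis region, i.e. its distance to the
    region boundary is at least its NND (tangency counts as contained).
    NND values themselves are never modified.
    """
    poly = pattern.region_polygon()
    if poly.area <= 0:
        raise ValueError("region has zero area")
    ids = [r.cell_id for r in records]
    bdist = pattern.boundary_distance(pattern.points[ids])
    for r, bd in zip(records, bdist):
        r.included = bool(bd >= r.nnd * (1.0 - _TANGENT_RTOL))
    return records


def compute_lii(records: list[NNDRecord],
                low_cut: float = 7.0, high_cut: float = 9.0) -> LIIResult:
    """Tumor-level LII: arithmetic mean NND over included cells."""
    included = [r for r in records if r.included]
    if not included:
        raise ValueError("no cells remain after edge exclusion; LII undefined")
    lii = float(np.mean([r.nnd for r in included]))
    return LIIResult(
        lii=lii, n_total=len(records), n_included=len(included),
        bin=classify_lii(lii, low_cut, high_cut), per_cell=records,
    )


def classify_lii(lii: float, low_cut: float = 7.0, high_cut: float = 9.0) -> str:
    """Bin a tumor by LII: low (<= low_cut), high (>= high_cut), else
    intermediate."""
    if low_cut > high_cut:
        raise ValueError("low_cut must not exceed high_cut")
    if lii <= low_cut:
        return "low"
    if lii >= high_cut:
        return "high"
    return "intermediate"


def analyze_pattern(pattern: PointPattern, edge_exclusion: bool = True,
                    low_cut: float = 7.0, high_cut: float = 9.0) -> LIIResult:
    """NND -> border correction -> LII, in one call."""
    records = compute_nnd(pattern)
    if edge_exclusion:
        records = apply_edge_exclusion(records, pattern)
    return compute_lii(records, low_cut=low_cut, high_cut=high_cut)


def _summarize(values: np.ndarray, bin_edges: np.ndarray) -> PopulationSummary:
    values = np.asarray(values, dtype=float)
    med = float(np.median(values))
    # exactly-median cells go to the lower subset
    above = values[values > med]
    below = values[values <= med]
    counts, _ = np.histogram(values, bins=bin_edges)
    return PopulationSummary(
        n=len(values), mean=float(values.mean()), median=med,
        above_median=above, below_median=below,
        bin_edges=bin_edges, histogram_counts=counts,
        histogram_percent=100.0 * counts / len(values),
    )


def population_analysis(
    nnd_before: np.ndarray,
    nnd_after: np.ndarray,
    bin_edges: np.ndarray | None = None,
) -> tuple[PopulationSummary, PopulationSummary, float, float]:
    """Per-cell NND population comparison between two conditions.

    Summarizes each group (median split with exactly-median cells assigned
    to the lower subset; percentage histogram over configurable um bins,
    default edges 0/7/9/inf matching the LII bins) and compares the two
    distributions with Welch's unequal-variance t test.

    Returns (summary_before, summary_after, welch_t, p).
    """
    a = np.asarray(nnd_before, dtype=float)
    b = np.asarray(nnd_after, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 cells")
    if bin_edges is None:
        bin_edges = np.array([0.0, 7.0, 9.0, np.inf])
    bin_edges = np.asarray(bin_edges, dtype=float)
    t, p = _welch(a, b)
    return _summarize(a, bin_edges), _summarize(b, bin_edges), t, p


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("both groups have zero variance; Welch test undefined")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compare_lii_groups(
    lii_a: np.ndarray, lii_b: np.ndarray
) -> tuple[float, float, float]:
    """Cohort-level contrast of two LII samples.

    Returns (difference of means a-b, Welch t statistic, two-sided p).
    """
    a = np.asarray(lii_a, dtype=float)
    b = np.asarray(lii_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = _welch(a, b)
    return float(a.mean() - b.mean()), t, p
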