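"""Cross-sectional MT packing statistics for a K-fiber.

Works on the MT center coordinates collected at the tomogram midplane:
bundle membership (a K-fiber is a proximity component of >= 10 MTs within
105 nm center-to-center, i.e. an 80 nm boundary around each 25-nm MT),
convex-hull area and MT density, nearest-neighbour spacing, neighbour
counts at a search radius, and Voronoi-interpolated neighbour-count heat
maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import griddata
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

MT_DIAMETER_NM = 25.0
BUNDLE_RADIUS_NM = 105.0   # 80 nm boundary around a 25 nm MT, center-to-center
KFIBER_MIN_MTS = 10

__all__ = [
    "CrossSectionMap",
    "PackingStats",
    "define_bundle",
    "hull_area",
    "nearest_neighbor_stats",
    "neighbor_counts",
    "packing_heatmap",
]


@dataclass
class CrossSectionMap:
    """MT center positions (nm) at the tomogram midplane of one fiber."""

    fiber_id: str
    mt_ids: list
    points: np.ndarray                  # (n, 2) nm
    mt_diameter_nm: float = MT_DIAMETER_NM

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if len(self.mt_ids) != len(self.points):
            raise ValueError("mt_ids and points length mismatch")
        if len(self.points) < 1:
            raise ValueError("need at least one MT")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite coordinates")


@dataclass
class PackingStats:
    """Per-fiber packing summary (Fig. 3-style quantities)."""

    fiber_id: str
    n_mts: int
    hull_area_nm2: float
    density_mts_per_um2: float          # NaN when hull area is 0
    nn_distances_nm: np.ndarray
    neighbor_counts: np.ndarray
    neighbor_radius_nm: float
    median_nn_nm: float
    median_edge_to_edge_nm: float
    extras: dict = field(default_factory=dict)


def _pairwise(points: np.ndarray) -> np.ndarray:
    d = squareform(pdist(np.asarray(points, dtype=float)))
    np.fill_diagonal(d, np.inf)
    return d


def define_bundle(points, radius_nm: float = BUNDLE_RADIUS_NM,
                  min_kfiber_mts: int = KFIBER_MIN_MTS) -> list[dict]:
    """Partition MTs into proximity bundles and flag K-fibers.

    Bundles are connected components of the graph linking centers within
    ``radius_nm`` (closed ball).  A bundle is a K-fiber when it holds at
    least ``min_kfiber_mts`` MTs.  Returns a list of
    ``{"indices": [...], "is_kfiber": bool}`` sorted by smallest index.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n == 0:
        raise ValueError("need at least one point")
    if n == 1:
        return [{"indices": [0], "is_kfiber": 1 >= min_kfiber_mts}]
    adj = _pairwise(points) <= radius_nm
    n_comp, labels = connected_components(adj, directed=False)
    bundles = []
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c).tolist()
        bundles.append({"indices": idx, "is_kfiber": len(idx) >= min_kfiber_mts})
    bundles.sort(key=lambda b: b["indices"][0])
    return bundles


def hull_area(points) -> float:
    """Area (nm^2) of the 2D convex hull of MT centers.

    Fewer than 3 points, or collinear points, give area 0 with a warning
    (MT density is then undefined).
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        warnings.warn("fewer than 3 points: hull area 0, density undefined")
        return 0.0
    try:
        return float(ConvexHull(points).volume)  # 2D: .volume is the area
    except QhullError:
        warnings.warn("degenerate (collinear) points: hull area 0")
        return 0.0


def nearest_neighbor_stats(points, mt_diameter_nm: float = MT_DIAMETER_NM) -> dict:
    """Per-MT nearest-neighbour distances and medians.

    Edge-to-edge values subtract one MT diameter from the center-to-center
    distance.  A single point returns empty statistics.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return {
            "nn_nm": np.array([]),
            "median_nn_nm": float("nan"),
            "median_edge_to_edge_nm": float("nan"),
        }
    nn = _pairwise(points).min(axis=1)
    med = float(np.median(nn))
    return {
        "nn_nm": nn,
        "median_nn_nm": med,
        "median_edge_to_edge_nm": med - mt_diameter_nm,
    }


def neighbor_counts(points, radius_nm: float) -> np.ndarray:
    """Number of other MTs with center distance <= radius_nm, per MT."""
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return np.zeros(len(points), dtype=int)
    return (_pairwise(points) <= radius_nm).sum(axis=1)


def packing_heatmap(points, radius_nm: float = BUNDLE_RADIUS_NM,
                    grid_nm: float = 10.0) -> dict:
    """Voronoi (nearest-seed) interpolation of neighbour counts on a grid.

    The per-MT neighbour count at ``radius_nm`` is spread over a regular
    grid covering the bounding box of the points padded by the radius;
    every grid node takes the count of its nearest MT, so the field is
    exact at the seed positions.  Returns ``{"x", "y", "field"}`` with
    ``field`` shaped (len(y), len(x)).
    """
    points = np.asarray(points, dtype=float)
    counts = neighbor_counts(points, radius_nm) if len(points) > 1 else np.zeros(1)
    lo = points.min(axis=0) - radius_nm
    hi = points.max(axis=0) + radius_nm
    x = np.arange(lo[0], hi[0] + grid_nm, grid_nm)
    y = np.arange(lo[1], hi[1] + grid_nm, grid_nm)
    gx, gy = np.meshgrid(x, y)
    field = griddata(points, counts.astype(float), (gx, gy), method="nearest")
    return {"x": x, "y": y, "field": field}


def packing_stats(cross_section: CrossSectionMap,
                  neighbor_radius_nm: float = BUNDLE_RADIUS_NM) -> PackingStats:
    """Full per-fiber packing summary."""
    pts = cross_section.points
    area = hull_area(pts)
    nn = nearest_neighbor_stats(pts, cross_section.mt_diameter_nm)
    # nm^2 -> um^2: 1 um^2 = 1e6 nm^2
    density = len(pts) / (area / 1e6) if area > 0 else float("nan")
    return PackingStats(
        fiber_id=cross_section.fiber_id,
        n_mts=len(pts),
        hull_area_nm2=area,
        density_mts_per_um2=density,
        nn_distances_nm=nn["nn_nm"],
        neighbor_counts=neighbor_counts(pts, neighbor_radius_nm),
        neighbor_radius_nm=neighbor_radius_nm,
        median_nn_nm=nn["median_nn_nm"],
        median_edge_to_edge_nm=nn["median_edge_to_edge_nm"],
    )


__all__.append("packing_stats")
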