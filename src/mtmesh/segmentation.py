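"""Mesh segmentation and connector classification in tomogram-like volumes.

Given a density volume and per-MT label masks (MTs are rendered/traced
upstream), the mesh is every connected density component that (a) lies at
or above a threshold anchored at the mean gray value of the MT-labeled
voxels, (b) is not itself MT, and (c) touches at least one MT surface.
Components touching exactly one MT are "pendants"; components touching
two, three, four or more MTs are connectors of that polarity.  Volumes are
voxel counts times the voxel volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely import MultiPoint

__all__ = [
    "DensityVolume",
    "MTLabelMask",
    "MeshMask",
    "Connector",
    "SegmentationStats",
    "SegmentationOptions",
    "segment_mesh",
    "classify_connectors",
    "mesh_volume_ratios",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

# 26-neighbourhood offsets (excluding the origin)
_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


@dataclass
class DensityVolume:
    """Scalar density on a regular grid with isotropic voxels (nm)."""

    values: np.ndarray       # (nx, ny, nz)
    voxel_nm: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("density must be a 3D array")
        if self.voxel_nm <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_nm3(self) -> float:
        return self.voxel_nm**3


@dataclass
class MTLabelMask:
    """Integer labels on the same grid: 0 = background, k = MT k."""

    labels: np.ndarray       # (nx, ny, nz) int
    voxel_nm: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int32)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")

    @property
    def mt_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]


@dataclass
class MeshMask:
    """Binary mesh voxels plus the threshold that produced them."""

    mask: np.ndarray         # bool, same dims as density
    threshold: float
    voxel_nm: float


@dataclass
class Connector:
    """One uninterrupted mesh component contacting >= 2 MTs."""

    connector_id: int
    voxel_indices: np.ndarray        # (m, 3) int voxel coordinates
    volume_nm3: float
    touched_mts: frozenset

    @property
    def polarity(self) -> int:
        return len(self.touched_mts)


@dataclass
class SegmentationOptions:
    threshold_factor: float = 1.0        # x mean MT gray value
    hysteresis_low_factor: float = 0.65  # grow seeds into low x threshold; 1 disables
    min_component_voxels: int = 8        # ~one (5 nm)^3 strut element
    wall_nm: float = 5.0                 # analytic MT wall thickness
    mt_outer_radius_nm: float = 12.5
    fiber_margin_nm: float = 12.5        # hull dilation for "fiber volume"


def _check_dims(volume: DensityVolume, mask: MTLabelMask) -> None:
    if volume.dims != mask.labels.shape:
        raise ValueError(
            f"density dims {volume.dims} != label dims {mask.labels.shape}"
        )


def segment_mesh(volume: DensityVolume, mask: MTLabelMask,
                 opts: SegmentationOptions | None = None) -> MeshMask:
    """Threshold-and-attach mesh detection.

    The anchor threshold is ``threshold_factor`` x the mean density over
    MT-labeled voxels.  Mesh voxels are members of 26-connected components
    of the super-threshold, non-MT candidate set that (a) contain at least
    one voxel at or above the anchor threshold, (b) 26-touch at least one
    MT surface, and (c) hold at least ``min_component_voxels`` voxels;
    unattached density (the "non-mesh" control) is discarded.  With
    ``hysteresis_low_factor`` < 1 the candidate set is grown from the
    anchor-threshold seeds down to ``low_factor`` x threshold, which keeps
    thin struts unbroken under noise; at 1.0 this reduces to the plain
    anchor threshold.
    """
    opts = opts or SegmentationOptions()
    _check_dims(volume, mask)
    mt = mask.labels > 0
    if not mt.any():
        raise ValueError("empty MT mask: cannot anchor the threshold")
    threshold = opts.threshold_factor * float(volume.values[mt].mean())
    empty = MeshMask(np.zeros(volume.dims, dtype=bool), threshold, volume.voxel_nm)
    if threshold > float(volume.values.max()):
        warnings.warn("threshold above volume maximum: empty mesh")
        return empty
    low = min(opts.hysteresis_low_factor, 1.0) * threshold
    candidate = (volume.values >= low) & ~mt
    comp, n_comp = ndimage.label(candidate, structure=_STRUCT_26)
    if n_comp == 0:
        return empty
    seeded = np.unique(comp[candidate & (volume.values >= threshold)])
    seeded = seeded[seeded > 0]
    touch_zone = ndimage.binary_dilation(mt, structure=_STRUCT_26) & ~mt
    touching = np.unique(comp[touch_zone & candidate])
    touching = touching[touching > 0]
    keep = np.intersect1d(seeded, touching)
    if keep.size == 0:
        return empty
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=keep)
    keep = keep[sizes >= opts.min_component_voxels]
    mesh = np.isin(comp, keep)
    return MeshMask(mesh, threshold, volume.voxel_nm)


def _touched_mts_per_component(comp: np.ndarray, labels: np.ndarray) -> dict:
    """Map component id -> set of MT labels 26-adjacent to it."""
    touched: dict[int, set] = {}
    for off in _OFFSETS_26:
        src = tuple(slice(max(o, 0), c + min(o, 0)) for o, c in zip(off, comp.shape))
        dst = tuple(slice(max(-o, 0), c + min(-o, 0)) for o, c in zip(off, comp.shape))
        c_part = comp[src]
        l_part = labels[dst]
        sel = (c_part > 0) & (l_part > 0)
        if not sel.any():
            continue
        pairs = np.unique(np.stack([c_part[sel], l_part[sel]], axis=1), axis=0)
        for cid, lab in pairs:
            touched.setdefault(int(cid), set()).add(int(lab))
    return touched


def classify_connectors(mesh: MeshMask, mask: MTLabelMask) -> dict:
    """Split the mesh into connectors (>= 2 MTs touched) and pendants (1).

    Components are never merged: two disjoint struts between the same MT
    pair are two connectors.  Returns ``{"connectors": [Connector ...],
    "pendants": [Connector ...]}`` with connector volumes in nm^3.
    """
    comp, n_comp = ndimage.label(mesh.mask, structure=_STRUCT_26)
    touched = _touched_mts_per_component(comp, mask.labels)
    voxel_vol = mesh.voxel_nm**3
    connectors, pendants = [], []
    for cid in range(1, n_comp + 1):
        idx = np.argwhere(comp == cid)
        mts = frozenset(touched.get(cid, set()))
        rec = Connector(
            connector_id=cid,
            voxel_indices=idx,
            volume_nm3=len(idx) * voxel_vol,
            touched_mts=mts,
        )
        (connectors if len(mts) >= 2 else pendants).append(rec)
    return {"connectors": connectors, "pendants": pendants}


@dataclass
class SegmentationStats:
    """Mesh volume bookkeeping for one fiber (Fig. 2-style quantities)."""

    fiber_id: str
    total_mesh_volume_nm3: float
    mt_wall_volume_nm3: float
    filled_mt_volume_nm3: float
    fiber_volume_nm3: float
    mesh_to_mt_wall_ratio: float
    mesh_to_filled_mt_ratio: float
    mesh_percent_of_fiber_volume: float
    polarity_counts: dict
    polarity_proportions: dict
    connector_volumes_nm3: dict      # polarity -> list of volumes
    n_pendants: int = 0
    pendant_volume_nm3: float = 0.0
    extras: dict = field(default_factory=dict)


def mesh_volume_ratios(connectors: dict, mesh: MeshMask, mask: MTLabelMask,
                       mt_centers_2d, mt_axis_lengths_nm,
                       slab_thickness_nm: float,
                       opts: SegmentationOptions | None = None,
                       fiber_id: str = "") -> SegmentationStats:
    """Mesh volume relative to MT walls, filled MTs and the fiber volume.

    MT wall volume uses the analytic hollow cylinder (outer radius
    ``mt_outer_radius_nm``, wall ``wall_nm``) times each MT's axis length
    through the slab; the filled-MT volume uses solid cylinders.  Fiber
    volume is the 2D convex hull of the MT centers dilated by
    ``fiber_margin_nm``, times the slab thickness.
    """
    opts = opts or SegmentationOptions()
    centers = np.asarray(mt_centers_2d, dtype=float)
    lengths = np.asarray(mt_axis_lengths_nm, dtype=float)
    if len(centers) == 0 or lengths.sum() <= 0:
        raise ValueError("zero MT volume: need at least one MT with length > 0")
    voxel_vol = mesh.voxel_nm**3
    mesh_vol = float(mesh.mask.sum()) * voxel_vol
    r_out = opts.mt_outer_radius_nm
    r_in = max(r_out - opts.wall_nm, 0.0)
    wall_vol = float(np.pi * (r_out**2 - r_in**2) * lengths.sum())
    filled_vol = float(np.pi * r_out**2 * lengths.sum())
    hull = MultiPoint(centers).convex_hull.buffer(opts.fiber_margin_nm)
    fiber_vol = float(hull.area * slab_thickness_nm)
    conns = connectors["connectors"]
    pends = connectors.get("pendants", [])
    counts: dict[int, int] = {}
    volumes: dict[int, list] = {}
    for c in conns:
        counts[c.polarity] = counts.get(c.polarity, 0) + 1
        volumes.setdefault(c.polarity, []).append(c.volume_nm3)
    n = sum(counts.values())
    props = {k: v / n for k, v in counts.items()} if n else {}
    return SegmentationStats(
        fiber_id=fiber_id,
        total_mesh_volume_nm3=mesh_vol,
        mt_wall_volume_nm3=wall_vol,
        filled_mt_volume_nm3=filled_vol,
        fiber_volume_nm3=fiber_vol,
        mesh_to_mt_wall_ratio=mesh_vol / wall_vol,
        mesh_to_filled_mt_ratio=mesh_vol / filled_vol,
        mesh_percent_of_fiber_volume=100.0 * mesh_vol / fiber_vol,
        polarity_counts=dict(sorted(counts.items())),
        polarity_proportions=dict(sorted(props.items())),
        connector_volumes_nm3={k: sorted(v) for k, v in sorted(volumes.items())},
        n_pendants=len(pends),
        pendant_volume_nm3=float(sum(p.volume_nm3 for p in pends)),
    )
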