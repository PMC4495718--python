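"""Synthetic K-fiber generator with known ground truth.

No tomograms are publicly deposited for this kind of study, so every
downstream stage is exercised on synthetic fibers that emulate the
tomogram-derived inputs: bundles of 10-40 roughly parallel 25-nm MTs with
center-to-center nearest-neighbour spacings near 48-56 nm, a minority of
trajectory-deviant MTs, strut-like inter-MT connectors of mixed polarity
(bipolar/tripolar/quadrupolar), and rendered density volumes with per-MT
label masks.

Two preset regimes mirror the study conditions: ``CONTROL_REGIME``
(56.1 nm median spacing, 10% deviant MTs up to 0.15 rad, sparser
connectors) and ``OE_REGIME`` (48.1 nm spacing, 40% deviant MTs up to
0.35 rad, denser connectors), the synthetic analog of the
TACC3-overexpression contrast.

MT placement is sequential dart-throwing on a jittered hexagonal lattice
scaled to the requested spacing, which reproduces near-regular packing
with occasional doublet/triplet clusters without a physics simulation.
Coordinates are right-handed, in nm, z along the slab depth; voxel index =
floor(coord / voxel_nm) (0-based), voxel centers at (i + 0.5) * voxel_nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .connectivity import ChainPartition, ConnectorGraph, Hyperedge, chains_from_connectors
from .model import FiberModel, MTRecord
from .segmentation import DensityVolume, MTLabelMask

__all__ = [
    "FiberSpec",
    "SyntheticFiber",
    "SyntheticVolume",
    "CONTROL_REGIME",
    "OE_REGIME",
    "generate_cross_section",
    "generate_mt_vectors",
    "generate_connector_graph",
    "generate_fiber",
    "render_volume",
]

BUNDLE_NEIGHBOR_NM = 105.0   # the paper-scale bundle-neighbour bound


class PackingInfeasibleError(RuntimeError):
    """Requested spacing/jitter cannot be packed without MT overlap."""


class RenderError(RuntimeError):
    """A connector could not be rendered cleanly (collision with MTs/struts)."""


@dataclass(frozen=True)
class FiberSpec:
    """Generator parameters for one synthetic K-fiber."""

    n_mts: int = 30
    mt_diameter_nm: float = 25.0
    mean_nn_spacing_nm: float = 56.1
    spacing_jitter_nm: float = 4.0
    slab_thickness_nm: float = 45.6
    fiber_tilt: tuple[float, float] = (0.0, 0.0)   # (polar, azimuthal) rad
    deviant_fraction: float = 0.1
    deviant_polar_max_rad: float = 0.15
    connector_polarity_mix: dict = field(
        default_factory=lambda: {2: 0.75, 3: 0.15, 4: 0.10}
    )
    connectors_per_mt: float = 0.6
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_mts < 1:
            raise ValueError("n_mts must be >= 1")
        for name in ("mt_diameter_nm", "mean_nn_spacing_nm", "slab_thickness_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.spacing_jitter_nm < 0:
            raise ValueError("spacing_jitter_nm must be >= 0")
        if not 0.0 <= self.deviant_fraction <= 1.0:
            raise ValueError("deviant_fraction must be in [0, 1]")
        mix = self.connector_polarity_mix
        if set(mix) - {2, 3, 4} or any(v < 0 for v in mix.values()):
            raise ValueError("polarity mix keys must be in {2, 3, 4}, values >= 0")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("polarity mix must sum to 1")
        if self.fiber_tilt[0] + self.deviant_polar_max_rad >= math.pi / 2:
            raise ValueError("tilt polar + deviant max must stay below pi/2")

    @classmethod
    def from_dict(cls, d: dict) -> "FiberSpec":
        d = dict(d)
        if "connector_polarity_mix" in d:
            d["connector_polarity_mix"] = {
                int(k): float(v) for k, v in d["connector_polarity_mix"].items()
            }
        if "fiber_tilt" in d:
            d["fiber_tilt"] = tuple(float(x) for x in d["fiber_tilt"])
        return cls(**d)

    def with_seed(self, seed: int) -> "FiberSpec":
        return replace(self, rng_seed=int(seed))


# connector rates are set so that chain sizes match the study conditions:
# sparse control mesh (chains of mostly 2-3 MTs, at most ~6, many singles)
# vs an interconnected OE mesh (chains up to ~12 MTs)
CONTROL_REGIME = FiberSpec(
    mean_nn_spacing_nm=56.1, deviant_fraction=0.1, deviant_polar_max_rad=0.15,
    connectors_per_mt=0.35,
)
OE_REGIME = FiberSpec(
    mean_nn_spacing_nm=48.1, deviant_fraction=0.4, deviant_polar_max_rad=0.35,
    connectors_per_mt=0.8,
)


def _rng(spec: FiberSpec, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.rng_seed) % (2**31), stage])


def _hex_lattice(n_sites: int, spacing: float) -> np.ndarray:
    """Hexagonal lattice sites sorted by (distance from origin, angle)."""
    m = int(math.ceil(math.sqrt(n_sites))) + 3
    pts = []
    for i in range(-m, m + 1):
        for j in range(-m, m + 1):
            x = spacing * (i + 0.5 * (j % 2))
            y = spacing * (math.sqrt(3) / 2) * j
            pts.append((x, y))
    pts = np.array(pts)
    d = np.hypot(pts[:, 0], pts[:, 1])
    ang = np.arctan2(pts[:, 1], pts[:, 0])
    order = np.lexsort((ang, np.round(d, 9)))
    return pts[order][:n_sites]


def generate_cross_section(spec: FiberSpec, max_attempts: int = 200) -> list[tuple]:
    """MT center positions at the slab midplane: jittered hexagonal packing.

    Returns ``[(mt_id, x_nm, y_nm), ...]`` with mt_ids 1..n.  Centers are
    lattice sites (nearest the origin first) plus isotropic Gaussian
    jitter; a jitter draw that brings any pair closer than one MT diameter
    is redrawn, and a bounded number of failures signals an over-dense
    spec.
    """
    sites = _hex_lattice(spec.n_mts, spec.mean_nn_spacing_nm)
    if spec.n_mts == 1:
        return [(1, float(sites[0, 0]), float(sites[0, 1]))]
    if spec.mean_nn_spacing_nm <= spec.mt_diameter_nm:
        raise PackingInfeasibleError(
            f"spacing {spec.mean_nn_spacing_nm} nm <= MT diameter "
            f"{spec.mt_diameter_nm} nm: bundle cannot be packed"
        )
    rng = _rng(spec, 1)
    for _ in range(max_attempts):
        pts = sites + rng.normal(0.0, spec.spacing_jitter_nm, size=sites.shape) \
            if spec.spacing_jitter_nm > 0 else sites.copy()
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        if spec.spacing_jitter_nm > 0:
            # jittering biases nearest-neighbour distances low (min over ~6
            # neighbours); rescale isotropically so the empirical median NN
            # equals the requested spacing exactly
            med = float(np.median(d.min(axis=1)))
            pts = pts * (spec.mean_nn_spacing_nm / med)
            d = d * (spec.mean_nn_spacing_nm / med)
        if d.min() >= spec.mt_diameter_nm:
            return [(i + 1, float(x), float(y)) for i, (x, y) in enumerate(pts)]
    raise PackingInfeasibleError(
        f"could not place {spec.n_mts} MTs at spacing "
        f"{spec.mean_nn_spacing_nm} +/- {spec.spacing_jitter_nm} nm "
        f"without overlap after {max_attempts} attempts"
    )


def _unit_from_angles(polar: float, azimuth: float) -> np.ndarray:
    return np.array([
        math.sin(polar) * math.cos(azimuth),
        math.sin(polar) * math.sin(azimuth),
        math.cos(polar),
    ])


def generate_mt_vectors(cross_section, spec: FiberSpec) -> list[tuple]:
    """Bottom/top 3D coordinates through the slab for each MT.

    Every MT runs along the bundle direction (the fiber tilt); a planted
    subset of exactly ``ceil(deviant_fraction * n)`` MTs receives an extra
    polar deviation drawn uniformly from (0, deviant_polar_max_rad] at a
    random azimuth.  Each MT passes through its cross-section center at
    the slab midplane and spans the full slab: |top.z - bottom.z| equals
    the slab thickness.  Returns ``[(mt_id, bottom_xyz, top_xyz), ...]``.
    """
    rng = _rng(spec, 2)
    n = len(cross_section)
    n_dev = math.ceil(spec.deviant_fraction * n - 1e-9)
    deviant_ids = set(
        rng.choice([mt_id for mt_id, _, _ in cross_section], size=n_dev, replace=False)
        .tolist()
    ) if n_dev else set()
    tilt_polar, tilt_azim = spec.fiber_tilt
    out = []
    for mt_id, x, y in cross_section:
        if mt_id in deviant_ids:
            extra = rng.uniform(0.0, spec.deviant_polar_max_rad)
            extra = max(extra, 1e-6)       # strictly > 0: planted deviants deviate
            azim = rng.uniform(0.0, 2 * math.pi)
            local = _unit_from_angles(extra, azim)
        else:
            local = np.array([0.0, 0.0, 1.0])
        # rotate the local direction by the bundle tilt: first tip by the
        # polar angle about y, then swing to the requested azimuth about z
        cb, sb = math.cos(tilt_polar), math.sin(tilt_polar)
        ca, sa = math.cos(tilt_azim), math.sin(tilt_azim)
        ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
        rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
        u = rz @ (ry @ local)
        mid = np.array([x, y, spec.slab_thickness_nm / 2.0])
        half = (spec.slab_thickness_nm / u[2]) / 2.0
        out.append((mt_id, tuple(mid - u * half), tuple(mid + u * half)))
    return out


def _proximal_cliques(points: dict, max_size: int,
                      radius: float = BUNDLE_NEIGHBOR_NM) -> dict:
    """All MT subsets of size 2..max_size with pairwise distance <= radius."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(points)
    ids = sorted(points)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if math.dist(points[a], points[b]) <= radius:
                g.add_edge(a, b)
    by_size: dict[int, list] = {k: [] for k in range(2, max_size + 1)}
    for clique in nx.enumerate_all_cliques(g):
        k = len(clique)
        if k > max_size:
            break
        if k >= 2:
            by_size[k].append(tuple(sorted(clique)))
    return by_size


def generate_connector_graph(fiber: FiberModel, spec: FiberSpec) -> ConnectorGraph:
    """Plant mesh connectors between mutually proximal MTs.

    Hyperedge size k in {2, 3, 4} is drawn from ``connector_polarity_mix``;
    the member set is sampled uniformly from the k-cliques of the 105-nm
    proximity graph (all pairwise center distances within the
    bundle-neighbour bound).  The hyperedge count is
    ``round(connectors_per_mt * n_mts)``.
    """
    if len(fiber.mts) < 2:
        raise ValueError("need >= 2 MTs to plant connectors")
    points = {m.mt_id: (m.mid_x_nm, m.mid_y_nm) for m in fiber.mts}
    cliques = _proximal_cliques(points, max_size=4)
    if not cliques[2]:
        raise RuntimeError(
            f"no MT pair within {BUNDLE_NEIGHBOR_NM} nm: nothing to connect"
        )
    rng = _rng(spec, 3)
    sizes = sorted(spec.connector_polarity_mix)
    probs = np.array([spec.connector_polarity_mix[k] for k in sizes])
    n_edges = int(round(spec.connectors_per_mt * len(fiber.mts)))
    edges = []
    for cid in range(1, n_edges + 1):
        k = int(rng.choice(sizes, p=probs))
        while not cliques.get(k):
            k -= 1      # no clique of that size: fall back to smaller polarity
        members = cliques[k][int(rng.integers(len(cliques[k])))]
        edges.append(Hyperedge(connector_id=cid, mt_ids=frozenset(members)))
    return ConnectorGraph(fiber_id=fiber.fiber_id, nodes=sorted(points),
                          hyperedges=edges)


@dataclass
class SyntheticFiber:
    """A generated fiber with its planted ground truth."""

    fiber_model: FiberModel
    true_connectors: ConnectorGraph
    true_chain_partition: ChainPartition
    spec: FiberSpec


def generate_fiber(spec: FiberSpec, fiber_id: str = "synthetic",
                   condition_label: str = "") -> SyntheticFiber:
    """Generate coordinates, a connector graph and the implied chains."""
    cross = generate_cross_section(spec)
    vectors = generate_mt_vectors(cross, spec)
    mts = [
        MTRecord(
            mt_id=int(mt_id), mid_x_nm=float(x), mid_y_nm=float(y),
            bot_x_nm=bot[0], bot_y_nm=bot[1], bot_z_nm=bot[2],
            top_x_nm=top[0], top_y_nm=top[1], top_z_nm=top[2],
        )
        for (mt_id, x, y), (_, bot, top) in zip(cross, vectors)
    ]
    fiber = FiberModel(
        fiber_id=fiber_id, mts=mts, slab_thickness_nm=spec.slab_thickness_nm,
        condition_label=condition_label,
    )
    if spec.n_mts >= 2:
        graph = generate_connector_graph(fiber, spec)
    else:
        graph = ConnectorGraph(fiber_id=fiber_id, nodes=[m.mt_id for m in mts])
    return SyntheticFiber(
        fiber_model=fiber,
        true_connectors=graph,
        true_chain_partition=chains_from_connectors(graph),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Volume rendering
# ---------------------------------------------------------------------------

@dataclass
class SyntheticVolume:
    """Rendered density + labels + planted connector ground truth."""

    density: DensityVolume
    mt_labels: MTLabelMask
    planted_connectors: list      # [{"connector_id", "mt_ids", "voxels"(m,3)}]
    origin_nm: np.ndarray         # world position of voxel (0,0,0) corner

    def planted_voxel_sets(self) -> list[set]:
        return [set(map(tuple, c["voxels"])) for c in self.planted_connectors]


# density levels before noise (arbitrary but fixed contrast, so that
# MT-anchored thresholding is exercised nontrivially)
BACKGROUND = 0.0
WALL = 1.0
LUMEN = 0.2
CONNECTOR = 0.8


def _segment_distance_sq(origin_nm, voxel_nm, shape, a, b, pad):
    """Squared distance from voxel centers (in a padded subbox) to segment ab.

    Returns (subbox slices, dist2 array over the subbox).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    lo_w = np.minimum(a, b) - pad
    hi_w = np.maximum(a, b) + pad
    lo = np.maximum(np.floor((lo_w - origin_nm) / voxel_nm).astype(int), 0)
    hi = np.minimum(np.ceil((hi_w - origin_nm) / voxel_nm).astype(int) + 1,
                    np.asarray(shape))
    if np.any(lo >= hi):
        return None, None
    axes = [
        origin_nm[k] + (np.arange(lo[k], hi[k]) + 0.5) * voxel_nm for k in range(3)
    ]
    px = axes[0][:, None, None]
    py = axes[1][None, :, None]
    pz = axes[2][None, None, :]
    u = b - a
    L2 = float(u @ u)
    dx, dy, dz = px - a[0], py - a[1], pz - a[2]
    norm2 = dx**2 + dy**2 + dz**2
    if L2 == 0:
        return tuple(slice(l, h) for l, h in zip(lo, hi)), norm2
    dot = dx * u[0] + dy * u[1] + dz * u[2]
    t = np.clip(dot, 0.0, L2) / L2
    dist2 = norm2 - 2 * t * dot + t**2 * L2
    return tuple(slice(l, h) for l, h in zip(lo, hi)), np.maximum(dist2, 0.0)


def _mt_axis_point_at_z(mt: MTRecord, z: float) -> np.ndarray:
    bot = np.array([mt.bot_x_nm, mt.bot_y_nm, mt.bot_z_nm])
    top = np.array([mt.top_x_nm, mt.top_y_nm, mt.top_z_nm])
    t = (z - bot[2]) / (top[2] - bot[2])
    return bot + t * (top - bot)


def _touched_labels(voxels: np.ndarray, labels: np.ndarray) -> set:
    """MT labels 26-adjacent to (or under) the given voxel coordinates."""
    shape = np.asarray(labels.shape)
    touched = set()
    for off in np.array(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1])).T.reshape(-1, 3):
        nb = voxels + off
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        vals = labels[tuple(nb[ok].T)]
        touched.update(int(v) for v in np.unique(vals) if v != 0)
    return touched


def render_volume(fiber: FiberModel, connectors: ConnectorGraph,
                  voxel_nm: float = 2.0, noise_sd: float = 0.0,
                  strut_radius_nm: float = 2.5, wall_nm: float = 5.0,
                  margin_nm: float = 20.0, seed: int | None = 0,
                  max_attempts: int = 25) -> SyntheticVolume:
    """Render a fiber and its connectors into a density volume + label mask.

    MTs become hollow tubes (outer diameter 25 nm, wall ``wall_nm`` at
    density 1.0, lumen 0.2 over background 0.0); each connector becomes a
    star of ~5-nm-thick struts (density 0.8) meeting at a junction near
    the centroid of its member MT axes at a random slab depth, carved
    outside all MT tubes.  Additive Gaussian noise at ``noise_sd`` is
    applied last.  Planted per-connector voxel sets are recorded; a
    junction whose struts would collide with a non-member MT or another
    planted connector is re-drawn up to ``max_attempts`` times, then a
    ``RenderError`` is raised.
    """
    r_out = 12.5
    if voxel_nm <= 0 or voxel_nm > r_out * 2 / 5:
        raise ValueError("voxel_nm must be in (0, mt_diameter/5]")
    rng = np.random.default_rng(seed)
    pts = np.array([[m.mid_x_nm, m.mid_y_nm] for m in fiber.mts])
    lo = np.array([pts[:, 0].min() - margin_nm - r_out,
                   pts[:, 1].min() - margin_nm - r_out, 0.0])
    hi = np.array([pts[:, 0].max() + margin_nm + r_out,
                   pts[:, 1].max() + margin_nm + r_out,
                   fiber.slab_thickness_nm])
    origin = np.floor(lo / voxel_nm) * voxel_nm
    shape = tuple(int(math.ceil((h - o) / voxel_nm))
                  for h, o in zip(hi, origin))
    density = np.full(shape, BACKGROUND, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.int32)

    r_in = max(r_out - wall_nm, 0.0)
    by_id = {m.mt_id: m for m in fiber.mts}
    for m in fiber.mts:
        a = np.array([m.bot_x_nm, m.bot_y_nm, m.bot_z_nm])
        b = np.array([m.top_x_nm, m.top_y_nm, m.top_z_nm])
        sl, d2 = _segment_distance_sq(origin, voxel_nm, shape, a, b, r_out + voxel_nm)
        if sl is None:
            continue
        inside = d2 <= r_out**2
        clash = inside & (labels[sl] > 0)
        if clash.any():
            other = int(labels[sl][clash][0])
            raise RenderError(f"MTs {other} and {m.mt_id} overlap in voxel space")
        wall = inside & (d2 > r_in**2)
        lumen = d2 <= r_in**2
        density[sl][wall] = WALL
        density[sl][lumen] = LUMEN
        labels[sl][inside] = m.mt_id

    planted = []
    connector_occupied = np.zeros(shape, dtype=bool)
    for edge in connectors.hyperedges:
        members = sorted(edge.mt_ids)
        placed = False
        z0 = rng.uniform()
        for attempt in range(max_attempts):
            # golden-ratio stratified slab depths: retries sweep the slab
            # instead of resampling near a conflicting connector
            frac = 0.2 + 0.6 * ((z0 + attempt * 0.6180339887) % 1.0)
            zj = frac * fiber.slab_thickness_nm
            anchors = [_mt_axis_point_at_z(by_id[m], zj) for m in members]
            junction = np.mean(anchors, axis=0)
            junction[:2] += rng.normal(0, 1.5, size=2)
            junction[2] = np.clip(zj, strut_radius_nm + voxel_nm,
                                  fiber.slab_thickness_nm - strut_radius_nm - voxel_nm)
            strut = np.zeros(shape, dtype=bool)
            for anchor in anchors:
                sl, d2 = _segment_distance_sq(origin, voxel_nm, shape,
                                              junction, anchor,
                                              strut_radius_nm + voxel_nm)
                if sl is None:
                    continue
                strut[sl] |= d2 <= strut_radius_nm**2
            strut &= labels == 0                      # carve MT volumes
            if not strut.any():
                continue
            vox = np.argwhere(strut)
            if (strut & connector_occupied).any():
                continue
            touched = _touched_labels(vox, labels)
            if touched != set(members):
                continue
            # keep planted components 26-separated so they stay distinct
            from scipy import ndimage
            grown = ndimage.binary_dilation(strut, structure=np.ones((3, 3, 3)))
            if (grown & connector_occupied).any():
                continue
            density[strut] = CONNECTOR
            connector_occupied |= strut
            planted.append({
                "connector_id": edge.connector_id,
                "mt_ids": frozenset(members),
                "voxels": vox,
            })
            placed = True
            break
        if not placed:
            raise RenderError(
                f"connector {edge.connector_id} {members} could not be placed "
                f"after {max_attempts} attempts"
            )
    if noise_sd > 0:
        density = density + rng.normal(0.0, noise_sd, size=shape).astype(np.float32)
    return SyntheticVolume(
        density=DensityVolume(values=density, voxel_nm=voxel_nm),
        mt_labels=MTLabelMask(labels=labels, voxel_nm=voxel_nm),
        planted_connectors=planted,
        origin_nm=origin,
    )
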