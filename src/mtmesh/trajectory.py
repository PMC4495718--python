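"""MT trajectory-deviation analysis via rotational normalization.

Each MT in a tomogram slab is reduced to the unit direction from its
bottom to its top 3D coordinate.  Because the fiber axis is oriented
arbitrarily with respect to the sectioning plane, the whole set is first
"zenith-normalized": an exhaustive grid search over Euler rotations
R = Rz(alpha) Ry(beta) Rx(gamma), 0 <= alpha <= 2*pi, 0 <= beta <= pi/2,
gamma = 0, in 1-degree steps, picks the rotation minimizing the summed
magnitude of the x-y projections of the directions, so that most MTs point
towards the zenith (+z).  Rotations act on row vectors (v' = v R), the
convention of the array languages this style of analysis comes from; this
is what makes the alpha search meaningful (the azimuthal rotation is
applied before the polar one).

After normalization, per-MT spherical angles (polar theta, azimuthal phi),
the intersection of each direction with an x-y plane at z = 100 nm, the
fraction of MTs intersecting within a 10 nm radius (a parallelism index),
and ordinary least-squares regressions of the angles against distance from
the fiber center (minimax / farthest-point 1-center) are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import stats

__all__ = [
    "MTVectorSet",
    "RotationGrid",
    "SphericalAngles",
    "TrajectoryStats",
    "euler_matrix",
    "bundle_center",
    "normalize_orientation",
    "spherical_angles",
    "plane_intersections",
    "radial_fraction",
    "angle_vs_distance_regression",
    "trajectory_stats",
]

Z_PLANE_NM = 100.0
RADIAL_THRESHOLD_NM = 10.0
GRID_STEP_RAD = np.pi / 180.0


@dataclass
class MTVectorSet:
    """Bottom/top 3D coordinates (nm) and derived unit directions."""

    fiber_id: str
    mt_ids: list
    bottoms: np.ndarray      # (n, 3) nm
    tops: np.ndarray         # (n, 3) nm
    directions: np.ndarray = field(init=False)   # (n, 3) unit vectors

    def __post_init__(self):
        self.bottoms = np.asarray(self.bottoms, dtype=float)
        self.tops = np.asarray(self.tops, dtype=float)
        if self.bottoms.shape != self.tops.shape or self.bottoms.shape[1:] != (3,):
            raise ValueError("bottoms/tops must both be (n, 3)")
        if np.any(self.tops[:, 2] - self.bottoms[:, 2] <= 0):
            raise ValueError("top z must exceed bottom z for every MT")
        vec = self.tops - self.bottoms
        norms = np.linalg.norm(vec, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-length MT vector")
        self.directions = vec / norms[:, None]


@dataclass
class RotationGrid:
    """Euler-angle search grid: alpha in [0, 2*pi], beta in [0, pi/2], gamma = 0."""

    step_rad: float = GRID_STEP_RAD
    alpha_max: float = 2 * np.pi
    beta_max: float = np.pi / 2

    def __post_init__(self):
        if self.step_rad <= 0:
            raise ValueError("step must be positive")

    @property
    def alphas(self) -> np.ndarray:
        # half-open [0, 2*pi): alpha = 2*pi duplicates alpha = 0
        return np.arange(0.0, self.alpha_max - 1e-12, self.step_rad)

    @property
    def betas(self) -> np.ndarray:
        return np.arange(0.0, self.beta_max + 1e-12, self.step_rad)


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(b: float) -> np.ndarray:
    c, s = np.cos(b), np.sin(b)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rx(g: float) -> np.ndarray:
    c, s = np.cos(g), np.sin(g)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def euler_matrix(alpha: float, beta: float, gamma: float = 0.0) -> np.ndarray:
    """R = Rz(alpha) Ry(beta) Rx(gamma); applied to row vectors as v' = v R."""
    return _rz(alpha) @ _ry(beta) @ _rx(gamma)


def bundle_center(points_2d) -> tuple[np.ndarray, np.ndarray]:
    """Minimax (1-center) bundle center and per-MT distances.

    The center minimizes the maximum distance to the MT positions — the
    solved objective of farthest-point clustering with one cluster; it is
    the center of the smallest enclosing circle.
    """
    points_2d = np.asarray(points_2d, dtype=float)
    if points_2d.ndim != 2 or points_2d.shape[1] != 2 or len(points_2d) == 0:
        raise ValueError("points must be (n, 2) with n >= 1")
    if len(points_2d) == 1:
        center = points_2d[0].copy()
    else:
        circle = shapely.minimum_bounding_circle(shapely.MultiPoint(points_2d))
        center = np.array([circle.centroid.x, circle.centroid.y])
    dists = np.linalg.norm(points_2d - center, axis=1)
    return center, dists


def _projection_objective(directions: np.ndarray, alphas: np.ndarray,
                          betas: np.ndarray) -> np.ndarray:
    """Objective(beta, alpha) = sum_i ||xy of (v_i Rz(alpha) Ry(beta))||.

    Row action: v Rz(alpha) rotates the xy components; the subsequent
    Ry(beta) mixes x and z.  Fully vectorized over the grid.
    """
    v = np.asarray(directions, dtype=float)
    ca, sa = np.cos(alphas), np.sin(alphas)                 # (A,)
    # u = v @ Rz(alpha): ux = x*ca + y*sa? row action: (x, y, z) @ Rz
    #   Rz = [[c,-s,0],[s,c,0],[0,0,1]] -> ux = x*c + y*s, uy = -x*s + y*c
    ux = v[:, 0][None, :] * ca[:, None] + v[:, 1][None, :] * sa[:, None]   # (A, n)
    uy = -v[:, 0][None, :] * sa[:, None] + v[:, 1][None, :] * ca[:, None]
    uz = np.broadcast_to(v[:, 2][None, :], ux.shape)
    cb, sb = np.cos(betas), np.sin(betas)                   # (B,)
    # w = u @ Ry(beta): wx = ux*c - uz*s, wy = uy, wz = ux*s + uz*c
    wx = ux[None] * cb[:, None, None] - uz[None] * sb[:, None, None]  # (B, A, n)
    wy = np.broadcast_to(uy[None], wx.shape)
    return np.sqrt(wx**2 + wy**2).sum(axis=2)               # (B, A)


def normalize_orientation(vectors: MTVectorSet | np.ndarray,
                          grid: RotationGrid | None = None) -> dict:
    """Exhaustive Euler-grid search aligning the fiber axis to the zenith.

    Returns ``{"alpha", "beta", "objective", "rotated"}`` where ``rotated``
    holds the unit directions after applying the optimal rotation.  Ties
    are broken by the smallest beta, then the smallest alpha (so an
    already-normalized set returns the identity).
    """
    grid = grid or RotationGrid()
    directions = vectors.directions if isinstance(vectors, MTVectorSet) else \
        np.asarray(vectors, dtype=float)
    if directions.ndim != 2 or directions.shape[1] != 3 or len(directions) == 0:
        raise ValueError("need (n, 3) directions")
    alphas, betas = grid.alphas, grid.betas
    obj = _projection_objective(directions, alphas, betas)
    best = obj.min()
    # exact ties occur by symmetry (e.g. all alphas at beta = 0)
    tied = np.argwhere(obj <= best + 1e-12 * max(best, 1.0))
    bi, ai = min(map(tuple, tied))          # smallest beta index, then alpha
    alpha, beta = float(alphas[ai]), float(betas[bi])
    rotated = directions @ euler_matrix(alpha, beta)
    return {
        "alpha": alpha,
        "beta": beta,
        "objective": float(obj[bi, ai]),
        "rotated": rotated,
    }


@dataclass
class SphericalAngles:
    """Per-MT spherical coordinates of (rotated) direction vectors."""

    r: np.ndarray
    theta: np.ndarray   # polar, [0, pi]
    phi: np.ndarray     # azimuthal, (-pi, pi]; 0 when x = y = 0


def spherical_angles(rotated: np.ndarray) -> SphericalAngles:
    """r = |v|, theta = arccos(z/r), phi = atan2(y, x) (0 at the zenith)."""
    v = np.asarray(rotated, dtype=float)
    r = np.linalg.norm(v, axis=1)
    if np.any(r == 0):
        raise ValueError("zero-length vector")
    theta = np.arccos(np.clip(v[:, 2] / r, -1.0, 1.0))
    phi = np.where((v[:, 0] == 0) & (v[:, 1] == 0), 0.0,
                   np.arctan2(v[:, 1], v[:, 0]))
    return SphericalAngles(r=r, theta=theta, phi=phi)


def plane_intersections(rotated: np.ndarray, z_plane_nm: float = Z_PLANE_NM) -> dict:
    """Intersection of each direction (from the origin) with the plane z = z_plane.

    Directions with z <= 0 cannot intersect the plane above the origin;
    they are excluded and counted.  Returns ``{"xy" (m, 2), "kept_idx",
    "n_excluded"}``.
    """
    v = np.asarray(rotated, dtype=float)
    keep = v[:, 2] > 0
    vk = v[keep]
    xy = vk[:, :2] * (z_plane_nm / vk[:, 2])[:, None]
    return {
        "xy": xy,
        "kept_idx": np.flatnonzero(keep),
        "n_excluded": int((~keep).sum()),
    }


def radial_fraction(xy: np.ndarray, threshold_nm: float = RADIAL_THRESHOLD_NM) -> float:
    """Fraction of plane intersections with radius strictly < threshold."""
    xy = np.asarray(xy, dtype=float)
    if len(xy) == 0:
        return float("nan")
    radii = np.linalg.norm(xy, axis=1)
    return float(np.mean(radii < threshold_nm))


def angle_vs_distance_regression(angles: np.ndarray, distances: np.ndarray) -> dict:
    """OLS fit of an angle against distance from the fiber center.

    Returns slope, intercept, r^2, p-value and 95% confidence-band
    parameters (standard errors of slope and intercept).  Zero variance in
    distance leaves the fit undefined (flagged).
    """
    angles = np.asarray(angles, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if len(angles) < 3:
        raise ValueError("need >= 3 MTs for a regression")
    if np.ptp(distances) == 0:
        return {"undefined": True}
    res = stats.linregress(distances, angles)
    n = len(angles)
    tcrit = stats.t.ppf(0.975, n - 2)
    return {
        "undefined": False,
        "slope": res.slope,
        "intercept": res.intercept,
        "r2": res.rvalue**2,
        "p_value": res.pvalue,
        "slope_stderr": res.stderr,
        "intercept_stderr": res.intercept_stderr,
        "t_crit_95": float(tcrit),
    }


@dataclass
class TrajectoryStats:
    """Per-fiber trajectory summary after zenith normalization."""

    fiber_id: str
    alpha: float
    beta: float
    objective: float
    theta: np.ndarray
    phi: np.ndarray
    distance_from_center_nm: np.ndarray
    intersections_xy: np.ndarray
    n_excluded: int
    fraction_within_10nm: float
    theta_regression: dict
    phi_regression: dict


def trajectory_stats(vectors: MTVectorSet, midpoints_2d,
                     grid: RotationGrid | None = None,
                     z_plane_nm: float = Z_PLANE_NM,
                     threshold_nm: float = RADIAL_THRESHOLD_NM) -> TrajectoryStats:
    """Run the full trajectory analysis for one fiber."""
    center, dists = bundle_center(midpoints_2d)
    norm = normalize_orientation(vectors, grid)
    ang = spherical_angles(norm["rotated"])
    inter = plane_intersections(norm["rotated"], z_plane_nm)
    frac = radial_fraction(inter["xy"], threshold_nm)
    n = len(ang.theta)
    if n >= 3 and np.ptp(dists) > 0:
        theta_reg = angle_vs_distance_regression(ang.theta, dists)
        phi_reg = angle_vs_distance_regression(ang.phi, dists)
    else:
        theta_reg = phi_reg = {"undefined": True}
    return TrajectoryStats(
        fiber_id=vectors.fiber_id,
        alpha=norm["alpha"],
        beta=norm["beta"],
        objective=norm["objective"],
        theta=ang.theta,
        phi=ang.phi,
        distance_from_center_nm=dists,
        intersections_xy=inter["xy"],
        n_excluded=inter["n_excluded"],
        fraction_within_10nm=frac,
        theta_regression=theta_reg,
        phi_regression=phi_reg,
    )
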