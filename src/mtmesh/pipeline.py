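"""Pipeline orchestration: generate -> (segment) -> pack -> chain -> trajectory.

A single ``PipelineConfig`` (YAML/JSON-friendly dict) drives all stages
for one or more conditions; a single global seed deterministically derives
per-fiber sub-seeds, so the same config + seed yields a byte-identical
report.  A failure in one fiber is logged and flagged without aborting the
others.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .connectivity import (
    chain_size_histogram,
    chained_vs_single_test,
    chains_from_connectors,
    polarity_proportions,
    randomize_membership,
    rank_sum_test,
)
from .model import AnalysisReport
from .packing import CrossSectionMap, packing_stats
from .segmentation import SegmentationOptions, classify_connectors, mesh_volume_ratios, segment_mesh
from .synthetic import FiberSpec, generate_fiber, render_volume
from .trajectory import MTVectorSet, RotationGrid, trajectory_stats

log = logging.getLogger("mtmesh")

__all__ = ["PipelineConfig", "run_pipeline", "compare_conditions"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``conditions`` maps a condition label to a generator spec dict plus
    ``n_fibers``; stage toggles and per-stage parameters mirror the module
    defaults.
    """

    conditions: dict                       # label -> {"spec": {...}, "n_fibers": int}
    seed: int = 0
    stages: dict = field(default_factory=lambda: {
        "segmentation": False, "packing": True,
        "connectivity": True, "trajectory": True,
    })
    packing_radius_nm: float = 105.0
    proximity_radii_nm: tuple = tuple(np.arange(20.0, 121.0, 10.0))
    n_permutations: int = 200
    grid_step_rad: float = np.pi / 180.0
    z_plane_nm: float = 100.0
    radial_threshold_nm: float = 10.0
    voxel_nm: float = 2.0
    noise_sd: float = 0.0
    segmentation_opts: SegmentationOptions = field(default_factory=SegmentationOptions)

    def __post_init__(self):
        if not self.conditions:
            raise ValueError("config must define at least one condition")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for label, block in self.conditions.items():
            if "spec" not in block or "n_fibers" not in block:
                raise ValueError(f"condition {label!r} needs 'spec' and 'n_fibers'")
            if block["n_fibers"] < 1:
                raise ValueError(f"condition {label!r}: n_fibers must be >= 1")
            FiberSpec.from_dict(block["spec"])   # validates parameter ranges

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "proximity_radii_nm" in d:
            d["proximity_radii_nm"] = tuple(float(r) for r in d["proximity_radii_nm"])
        if "segmentation_opts" in d and isinstance(d["segmentation_opts"], dict):
            d["segmentation_opts"] = SegmentationOptions(**d["segmentation_opts"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: v for k, v in self.__dict__.items() if k != "segmentation_opts"},
            default=str, sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _fiber_seed(global_seed: int, label: str, index: int) -> int:
    h = hashlib.sha256(f"{global_seed}/{label}/{index}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _analyze_fiber(synth, config: PipelineConfig) -> dict:
    fiber = synth.fiber_model
    out: dict = {"n_mts": len(fiber)}
    stages = config.stages
    if stages.get("packing", True):
        ps = packing_stats(
            CrossSectionMap(fiber.fiber_id, fiber.mt_ids, fiber.midpoints),
            neighbor_radius_nm=config.packing_radius_nm,
        )
        out["packing"] = {
            "n_mts": ps.n_mts,
            "hull_area_nm2": ps.hull_area_nm2,
            "density_mts_per_um2": ps.density_mts_per_um2,
            "median_nn_nm": ps.median_nn_nm,
            "median_edge_to_edge_nm": ps.median_edge_to_edge_nm,
        }
    if stages.get("connectivity", True):
        part = chains_from_connectors(synth.true_connectors)
        hist = chain_size_histogram([part])
        props = polarity_proportions([synth.true_connectors])
        out["connectivity"] = {
            "n_chained": sum(s for s in part.chain_sizes.values() if s >= 2),
            "n_single": len(part.singles),
            "max_chain_size": max(part.chain_sizes.values()),
            "chain_size_histogram": hist,
            "polarity_proportions": props["proportions"],
        }
    if stages.get("trajectory", True):
        ts = trajectory_stats(
            MTVectorSet(fiber.fiber_id, fiber.mt_ids, fiber.bottoms, fiber.tops),
            fiber.midpoints,
            grid=RotationGrid(step_rad=config.grid_step_rad),
            z_plane_nm=config.z_plane_nm,
            threshold_nm=config.radial_threshold_nm,
        )
        out["trajectory"] = {
            "alpha": ts.alpha, "beta": ts.beta, "objective": ts.objective,
            "median_theta_rad": float(np.median(ts.theta)),
            "fraction_within_10nm": ts.fraction_within_10nm,
            "n_excluded": ts.n_excluded,
            "r2_theta": ts.theta_regression.get("r2"),
            "r2_phi": ts.phi_regression.get("r2"),
        }
    if stages.get("segmentation", False):
        vol = render_volume(
            fiber, synth.true_connectors, voxel_nm=config.voxel_nm,
            noise_sd=config.noise_sd, seed=synth.spec.rng_seed,
        )
        mesh = segment_mesh(vol.density, vol.mt_labels, config.segmentation_opts)
        conns = classify_connectors(mesh, vol.mt_labels)
        stats = mesh_volume_ratios(
            conns, mesh, vol.mt_labels,
            fiber.midpoints, [m.axis_length_nm for m in fiber.mts],
            fiber.slab_thickness_nm, config.segmentation_opts,
            fiber_id=fiber.fiber_id,
        )
        out["segmentation"] = {
            "total_mesh_volume_nm3": stats.total_mesh_volume_nm3,
            "mesh_to_mt_wall_ratio": stats.mesh_to_mt_wall_ratio,
            "mesh_to_filled_mt_ratio": stats.mesh_to_filled_mt_ratio,
            "mesh_percent_of_fiber_volume": stats.mesh_percent_of_fiber_volume,
            "polarity_counts": stats.polarity_counts,
            "n_pendants": stats.n_pendants,
        }
    return out


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Run all enabled stages for every fiber of every condition."""
    report = AnalysisReport(provenance={
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    })
    per_condition: dict = {}
    for label in sorted(config.conditions):
        block = config.conditions[label]
        base = FiberSpec.from_dict(block["spec"])
        fibers = []
        failures = []
        for i in range(block["n_fibers"]):
            fid = f"{label}_{i:03d}"
            spec = base.with_seed(_fiber_seed(config.seed, label, i))
            try:
                synth = generate_fiber(spec, fiber_id=fid, condition_label=label)
                result = _analyze_fiber(synth, config)
                result["condition"] = label
                report.add_fiber(fid, **result)
                fibers.append((synth, result))
            except Exception as exc:  # noqa: BLE001 - per-fiber isolation
                log.warning("fiber %s failed: %s", fid, exc)
                failures.append({"fiber_id": fid, "error": str(exc)})
                report.add_fiber(fid, failed={"error": str(exc)}, condition=label)
        per_condition[label] = fibers
        if failures:
            report.provenance.setdefault("failures", []).extend(failures)

    if config.stages.get("connectivity", True):
        for label, fibers in sorted(per_condition.items()):
            pooled = _pooled_proximity(fibers, config)
            if pooled:
                report.provenance.setdefault("pooled_proximity", {})[label] = pooled
    if len(per_condition) >= 2:
        report.provenance["condition_comparison"] = compare_conditions(report)
    return report


def _pooled_proximity(fibers, config: PipelineConfig) -> dict | None:
    """Chained-vs-single test pooling MTs across a condition's fibers."""
    pts, ids, parts = [], [], []
    offset = 0
    merged_chained = []
    for synth, _ in fibers:
        fiber = synth.fiber_model
        part = chains_from_connectors(synth.true_connectors)
        for m in fiber.mts:
            pts.append([m.mid_x_nm + offset, m.mid_y_nm])
            ids.append((offset, m.mt_id))
            merged_chained.append(part.is_chained(m.mt_id))
        offset += 10_000.0   # separate fibers far beyond any search radius
    if not pts or not (any(merged_chained) and not all(merged_chained)):
        return None
    lookup = dict(zip(ids, merged_chained))

    class _Part:
        def is_chained(self, key):
            return lookup[key]
    results = chained_vs_single_test(
        np.array(pts), ids, _Part(), radii_nm=config.proximity_radii_nm,
    )
    rand = randomize_membership(
        np.array(pts), ids, _Part(), radii_nm=config.proximity_radii_nm,
        n_permutations=config.n_permutations, seed=config.seed,
    )
    return {
        "radii_nm": list(config.proximity_radii_nm),
        "p_values": [r.p_value for r in results],
        "p_randomized_median": [float(x) if x == x else None
                                for x in rand["median_p"]],
    }


_COMPARE_METRICS = [
    ("packing", "median_nn_nm"),
    ("packing", "hull_area_nm2"),
    ("trajectory", "median_theta_rad"),
    ("trajectory", "fraction_within_10nm"),
    ("connectivity", "max_chain_size"),
]


def compare_conditions(report: AnalysisReport) -> dict:
    """Cross-condition rank-sum comparisons of per-fiber summary metrics."""
    by_cond: dict = {}
    for fid, stages in report.fibers.items():
        label = stages.get("condition")
        if label is None or "failed" in stages:
            continue
        by_cond.setdefault(label, []).append(stages)
    labels = sorted(by_cond)
    if len(labels) < 2:
        return {"skipped": "fewer than two conditions with results"}
    a, b = labels[:2]
    out = {"conditions": [a, b], "metrics": {}}
    for stage, metric in _COMPARE_METRICS:
        xa = [f[stage][metric] for f in by_cond[a]
              if stage in f and f[stage].get(metric) is not None]
        xb = [f[stage][metric] for f in by_cond[b]
              if stage in f and f[stage].get(metric) is not None]
        if not xa or not xb:
            continue
        u, p = rank_sum_test(xa, xb)
        out["metrics"][f"{stage}.{metric}"] = {
            "median_" + a: float(np.median(xa)),
            "median_" + b: float(np.median(xb)),
            "statistic": u,
            "p_value": p,
        }
    return out
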