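"""File formats: TSV fiber tables, JSON connector graphs, MRC volumes, reports.

Fiber tables are TSV with one row per MT (all coordinates in nm);
connector graphs are JSON hyperedge lists; volumes are MRC2014 maps
(density float32; labels stored as a paired float32 map holding integer
values, cast back on read) with the voxel size in the header, via gemmi.
Round-trips are lossless at the stated precision, and schema violations
never yield partially loaded objects.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .connectivity import ConnectorGraph, Hyperedge
from .model import AnalysisReport, FiberModel, MTRecord
from .segmentation import DensityVolume, MTLabelMask

__all__ = [
    "SchemaError",
    "read_fiber_table",
    "write_fiber_table",
    "read_connector_graph",
    "write_connector_graph",
    "read_volume",
    "write_volume",
    "write_report",
    "read_report",
]

FIBER_COLUMNS = [
    "mt_id", "mid_x_nm", "mid_y_nm",
    "bot_x_nm", "bot_y_nm", "bot_z_nm",
    "top_x_nm", "top_y_nm", "top_z_nm",
]

SCHEMA_VERSION = "1"


class SchemaError(ValueError):
    """A file does not conform to the expected schema."""


def write_fiber_table(fiber: FiberModel, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# mtmesh fiber table v{SCHEMA_VERSION}\n")
        fh.write(f"# fiber_id={fiber.fiber_id}\n")
        fh.write(f"# slab_thickness_nm={fiber.slab_thickness_nm!r}\n")
        fh.write(f"# condition_label={fiber.condition_label}\n")
        if fiber.voxel_nm is not None:
            fh.write(f"# voxel_nm={fiber.voxel_nm!r}\n")
        fh.write("\t".join(FIBER_COLUMNS) + "\n")
        for m in fiber.mts:
            fh.write("\t".join(
                [str(m.mt_id)] + [repr(float(getattr(m, c))) for c in FIBER_COLUMNS[1:]]
            ) + "\n")


def read_fiber_table(path, schema_version: str = SCHEMA_VERSION) -> FiberModel:
    """Read and validate a TSV fiber table.

    Errors name the offending row/column; no partially loaded object is
    ever returned.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = {}
    with path.open() as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            stripped = line[1:].strip()
            if "=" in stripped:
                k, v = stripped.split("=", 1)
                meta[k.strip()] = v.strip()
            elif "fiber table v" in stripped:
                ver = stripped.rsplit("v", 1)[-1]
                if ver != schema_version:
                    raise SchemaError(f"schema version {ver} != {schema_version}")
        else:
            body_start = i
            break
    df = pd.read_csv(path, sep="\t", skiprows=body_start, dtype=str)
    missing = [c for c in FIBER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")
    records = []
    for row_i, row in df.iterrows():
        vals = {}
        for c in FIBER_COLUMNS:
            try:
                vals[c] = int(row[c]) if c == "mt_id" else float(row[c])
            except (TypeError, ValueError):
                raise SchemaError(
                    f"non-numeric value {row[c]!r} at row {row_i}, column {c!r}"
                ) from None
        records.append(MTRecord(**vals))
    ids = [r.mt_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SchemaError(f"duplicate mt_id(s) {dupes} in {path}")
    if "slab_thickness_nm" not in meta:
        raise SchemaError(f"missing slab_thickness_nm header in {path}")
    return FiberModel(
        fiber_id=meta.get("fiber_id", path.stem),
        mts=records,
        slab_thickness_nm=float(meta["slab_thickness_nm"]),
        condition_label=meta.get("condition_label", ""),
        voxel_nm=float(meta["voxel_nm"]) if "voxel_nm" in meta else None,
    )


def write_connector_graph(graph: ConnectorGraph, path) -> None:
    doc = {
        "fiber_id": graph.fiber_id,
        "nodes": sorted(graph.nodes),
        "hyperedges": [
            {
                "connector_id": e.connector_id,
                "mt_ids": sorted(e.mt_ids),
                "volume_nm3": e.volume_nm3,
            }
            for e in sorted(graph.hyperedges, key=lambda e: e.connector_id)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_connector_graph(path) -> ConnectorGraph:
    doc = json.loads(Path(path).read_text())
    try:
        return ConnectorGraph(
            fiber_id=doc["fiber_id"],
            nodes=doc["nodes"],
            hyperedges=[
                Hyperedge(
                    connector_id=e["connector_id"],
                    mt_ids=frozenset(e["mt_ids"]),
                    volume_nm3=e.get("volume_nm3"),
                )
                for e in doc["hyperedges"]
            ],
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed connector graph {path}: {exc}") from exc


def write_volume(volume: DensityVolume, path,
                 labels: MTLabelMask | None = None) -> None:
    """Write an MRC map (and optionally a paired ``<stem>_labels.mrc``)."""
    path = Path(path)

    def _write(arr: np.ndarray, voxel_nm: float, p: Path) -> None:
        m = gemmi.Ccp4Map()
        m.grid = gemmi.FloatGrid(np.ascontiguousarray(arr, dtype=np.float32))
        nx, ny, nz = arr.shape
        m.grid.unit_cell = gemmi.UnitCell(
            nx * voxel_nm, ny * voxel_nm, nz * voxel_nm, 90, 90, 90
        )
        m.update_ccp4_header()
        m.write_ccp4_map(str(p))

    _write(volume.values, volume.voxel_nm, path)
    if labels is not None:
        if labels.labels.shape != volume.values.shape:
            raise ValueError(
                f"label dims {labels.labels.shape} != density dims "
                f"{volume.values.shape}"
            )
        _write(labels.labels.astype(np.float32), labels.voxel_nm,
               path.with_name(path.stem + "_labels.mrc"))


def _read_map(path) -> tuple[np.ndarray, float]:
    m = gemmi.read_ccp4_map(str(path))
    arr = np.array(m.grid, copy=True)
    spacings = np.array(m.grid.spacing)
    if not np.all(spacings > 0):       # zero cell reads back as NaN spacing
        raise SchemaError(
            f"{path}: missing voxel size in MRC header; pass voxel_nm explicitly"
        )
    if not np.allclose(spacings, spacings[0], rtol=1e-6):
        raise SchemaError(f"{path}: anisotropic voxels {spacings} unsupported")
    return arr, float(spacings[0])


def read_volume(path, labels_path=None,
                voxel_nm: float | None = None) -> tuple[DensityVolume, MTLabelMask | None]:
    """Read an MRC density (and optional paired label map).

    The voxel size comes from the header; a zero/absent header voxel size
    is an error unless ``voxel_nm`` overrides it.  Label dimensions must
    match the density exactly.
    """
    path = Path(path)
    try:
        arr, vox = _read_map(path)
    except SchemaError:
        if voxel_nm is None:
            raise
        m = gemmi.read_ccp4_map(str(path))
        arr, vox = np.array(m.grid, copy=True), float(voxel_nm)
    if voxel_nm is not None:
        vox = float(voxel_nm)
    density = DensityVolume(values=arr, voxel_nm=vox)
    labels = None
    if labels_path is None:
        candidate = path.with_name(path.stem + "_labels.mrc")
        labels_path = candidate if candidate.exists() else None
    if labels_path is not None:
        larr, _ = _read_map(labels_path)
        if larr.shape != arr.shape:
            raise SchemaError(
                f"label dims {larr.shape} != density dims {arr.shape}"
            )
        labels = MTLabelMask(labels=np.rint(larr).astype(np.int32), voxel_nm=vox)
    return density, labels


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted(_jsonable(v) for v in obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (obj != obj):   # NaN -> null
        return None
    return obj


def write_report(report: AnalysisReport, out_dir) -> Path:
    """Write report JSON plus per-fiber / per-MT TSV summaries.

    Key order is deterministic, so re-serialization of a parsed report is
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc = {
        "fibers": _jsonable(report.fibers),
        "provenance": _jsonable(report.provenance),
    }
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")

    rows = []
    for fid in sorted(report.fibers):
        stages = report.fibers[fid]
        row = {"fiber_id": fid}
        for stage in sorted(stages):
            data = stages[stage]
            if isinstance(data, dict):
                for k in sorted(data):
                    v = data[k]
                    if isinstance(v, (int, float, str)) or v is None:
                        row[f"{stage}.{k}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "per_fiber.tsv", sep="\t", index=False)
    return json_path


def read_report(path) -> AnalysisReport:
    doc = json.loads(Path(path).read_text())
    return AnalysisReport(fibers=doc["fibers"], provenance=doc["provenance"])
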