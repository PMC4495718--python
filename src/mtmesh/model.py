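"""In-memory containers for per-fiber coordinate data and analysis reports.

All lengths are nanometers.  A ``FiberModel`` holds, per MT, the
cross-section center at the tomogram midplane and the 3D bottom/top
coordinates across the slab.  Tomogram slabs in this kind of data are
roughly 29-66 nm thick; values outside that range are accepted with a
warning only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["MTRecord", "FiberModel", "AnalysisReport"]

SLAB_PLAUSIBLE_NM = (28.8, 66.4)


@dataclass(frozen=True)
class MTRecord:
    mt_id: int
    mid_x_nm: float
    mid_y_nm: float
    bot_x_nm: float
    bot_y_nm: float
    bot_z_nm: float
    top_x_nm: float
    top_y_nm: float
    top_z_nm: float

    @property
    def bottom(self) -> np.ndarray:
        return np.array([self.bot_x_nm, self.bot_y_nm, self.bot_z_nm])

    @property
    def top(self) -> np.ndarray:
        return np.array([self.top_x_nm, self.top_y_nm, self.top_z_nm])

    @property
    def midpoint(self) -> np.ndarray:
        return np.array([self.mid_x_nm, self.mid_y_nm])

    @property
    def axis_length_nm(self) -> float:
        return float(np.linalg.norm(self.top - self.bottom))


@dataclass
class FiberModel:
    """One K-fiber's MT coordinate data with tomogram metadata."""

    fiber_id: str
    mts: list[MTRecord]
    slab_thickness_nm: float
    condition_label: str = ""
    voxel_nm: float | None = None

    def __post_init__(self):
        ids = [m.mt_id for m in self.mts]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate mt_id(s) {dupes} in fiber {self.fiber_id!r}")
        for m in self.mts:
            if m.top_z_nm - m.bot_z_nm <= 0:
                raise ValueError(
                    f"MT {m.mt_id}: top z must exceed bottom z "
                    f"({m.top_z_nm} vs {m.bot_z_nm})"
                )
        lo, hi = SLAB_PLAUSIBLE_NM
        if not lo <= self.slab_thickness_nm <= hi:
            warnings.warn(
                f"slab thickness {self.slab_thickness_nm} nm outside the "
                f"plausible tomogram range {lo}-{hi} nm"
            )

    @property
    def mt_ids(self) -> list[int]:
        return [m.mt_id for m in self.mts]

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([[m.mid_x_nm, m.mid_y_nm] for m in self.mts])

    @property
    def bottoms(self) -> np.ndarray:
        return np.array([m.bottom for m in self.mts])

    @property
    def tops(self) -> np.ndarray:
        return np.array([m.top for m in self.mts])

    def __len__(self) -> int:
        return len(self.mts)


@dataclass
class AnalysisReport:
    """Per-fiber results of every pipeline stage plus provenance."""

    fibers: dict = field(default_factory=dict)   # fiber_id -> stage dicts
    provenance: dict = field(default_factory=dict)

    def add_fiber(self, fiber_id: str, **stages) -> None:
        self.fibers.setdefault(fiber_id, {}).update(stages)
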