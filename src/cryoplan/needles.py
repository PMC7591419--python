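"""Cryoprobe geometry and needle plans.

A needle is modelled as a fixed-temperature cylinder: the active
(freezing) segment extends from the tip backwards along the insertion
direction.  Two Galil-style probe types are supported, differing by the
length of the active tip; geometric defaults are configurable and not
vendor datasheet values.

Plans are stored as plain-text tables (one needle per row) with columns
``type, tip_x_mm, tip_y_mm, tip_z_mm, dir_x, dir_y, dir_z,
power_fraction`` in world mm coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import VoxelGrid

__all__ = ["Needle", "NeedlePlan", "rasterize_needle", "rasterize_plan",
           "read_plan", "write_plan", "NEEDLE_TYPES", "MAX_NEEDLES"]

#: active-tip lengths (mm) by probe type; IceRod has the longer tip
NEEDLE_TYPES = {"IceSeed": 15.0, "IceRod": 25.0}

#: 17-gauge shaft radius in mm
DEFAULT_RADIUS_MM = 0.735

#: at most nine probes can be placed in one plan
MAX_NEEDLES = 9


@dataclass(frozen=True)
class Needle:
    """One cryoprobe placement in world mm coordinates."""

    type: str
    tip_mm: tuple[float, float, float]
    direction: tuple[float, float, float]
    power_fraction: float = 1.0
    active_length_mm: float | None = None
    radius_mm: float = DEFAULT_RADIUS_MM

    def __post_init__(self) -> None:
        if self.type not in NEEDLE_TYPES:
            raise ValueError(f"unknown needle type {self.type!r}; "
                             f"expected one of {sorted(NEEDLE_TYPES)}")
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise ValueError(f"direction must be a unit vector, |d|={np.linalg.norm(d)}")
        if not (0.0 < self.power_fraction <= 1.0):
            raise ValueError("power_fraction must be in (0, 1]")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        length = self.active_length_mm
        if length is None:
            length = NEEDLE_TYPES[self.type]
        elif length <= 0:
            raise ValueError("active_length_mm must be positive")
        object.__setattr__(self, "active_length_mm", float(length))
        object.__setattr__(self, "tip_mm", tuple(float(x) for x in self.tip_mm))
        object.__setattr__(self, "direction", tuple(float(x) for x in self.direction))

    @property
    def base_mm(self) -> np.ndarray:
        """Proximal end of the active segment."""
        return np.asarray(self.tip_mm) - self.active_length_mm * np.asarray(self.direction)


@dataclass(frozen=True)
class NeedlePlan:
    needles: tuple[Needle, ...]

    def __post_init__(self) -> None:
        needles = tuple(self.needles)
        if not (1 <= len(needles) <= MAX_NEEDLES):
            raise ValueError(f"a plan holds 1..{MAX_NEEDLES} needles, got {len(needles)}")
        object.__setattr__(self, "needles", needles)

    def __len__(self) -> int:
        return len(self.needles)


def rasterize_needle(grid: VoxelGrid, needle: Needle) -> np.ndarray:
    """Boolean mask of voxels whose centre lies within the active cylinder.

    A voxel belongs to the probe if its centre is within ``radius_mm``
    of the tip-to-base segment (cylinder with hemispherical caps).  At
    sub-voxel radii the nearest voxel to each segment sample is included
    so a probe is never invisible to the solver.
    """
    X, Y, Z = grid.coordinate_fields()
    tip = np.asarray(needle.tip_mm)
    axis = np.asarray(needle.direction)
    L = needle.active_length_mm
    # distance from voxel centres to the segment [base, tip]
    px, py, pz = X - tip[0], Y - tip[1], Z - tip[2]
    t = px * axis[0] + py * axis[1] + pz * axis[2]  # signed, 0 at tip, -L at base
    t_clamped = np.clip(t, -L, 0.0)
    dx = px - t_clamped * axis[0]
    dy = py - t_clamped * axis[1]
    dz = pz - t_clamped * axis[2]
    dist2 = dx * dx + dy * dy + dz * dz
    mask = dist2 <= needle.radius_mm**2
    if not mask.any():
        # thin probe between voxel centres: snap samples along the segment
        n_samples = max(2, int(np.ceil(L / min(grid.spacing_mm))) + 1)
        mask = np.zeros(grid.shape, dtype=bool)
        for s in np.linspace(0.0, -L, n_samples):
            idx = np.rint(grid.world_to_index(tip + s * axis)).astype(int)
            if np.all(idx >= 0) and np.all(idx < np.array(grid.shape)):
                mask[tuple(idx)] = True
    return mask


def rasterize_plan(grid: VoxelGrid, plan: NeedlePlan) -> list[np.ndarray]:
    return [rasterize_needle(grid, n) for n in plan.needles]


_PLAN_COLUMNS = ["type", "tip_x_mm", "tip_y_mm", "tip_z_mm",
                 "dir_x", "dir_y", "dir_z", "power_fraction"]


def write_plan(plan: NeedlePlan, path: str | Path) -> None:
    rows = [
        {
            "type": n.type,
            "tip_x_mm": n.tip_mm[0], "tip_y_mm": n.tip_mm[1], "tip_z_mm": n.tip_mm[2],
            "dir_x": n.direction[0], "dir_y": n.direction[1], "dir_z": n.direction[2],
            "power_fraction": n.power_fraction,
        }
        for n in plan.needles
    ]
    pd.DataFrame(rows, columns=_PLAN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_plan(path: str | Path) -> NeedlePlan:
    df = pd.read_csv(path, sep="\t")
    missing = set(_PLAN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"needle plan {path} missing columns {sorted(missing)}")
    needles = []
    for _, row in df.iterrows():
        d = np.array([row.dir_x, row.dir_y, row.dir_z], dtype=float)
        d = d / np.linalg.norm(d)
        needles.append(
            Needle(
                type=str(row["type"]),
                tip_mm=(row.tip_x_mm, row.tip_y_mm, row.tip_z_mm),
                direction=tuple(d),
                power_fraction=float(row.power_fraction),
            )
        )
    return NeedlePlan(tuple(needles))
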