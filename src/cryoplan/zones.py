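"""Ablation-zone extraction and the lethal-isotherm cell-death model.

The simulated ablation zone (Sigma) is the region whose *minimum*
temperature over the whole freeze-thaw history fell to or below the
lethal isotherm; the ice ball is the region that reached 0 degC.  Since
the lethal isotherm is sub-freezing, Sigma is always contained in the
ice ball.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .grid import VoxelGrid

__all__ = [
    "AblationMask",
    "update_death",
    "extract_zone",
    "tumor_coverage",
    "circumscribing_sphere_diameter",
    "minimal_enclosing_sphere",
    "boundary_voxels",
]

MASK_LABELS = ("simulated", "reference", "tumor", "kidney", "iceball")


@dataclass(frozen=True)
class AblationMask:
    """Binary volumetric zone on a voxel grid."""

    grid: VoxelGrid
    voxels: np.ndarray
    label: str = "simulated"

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.shape != self.grid.shape:
            raise ValueError(f"mask shape {v.shape} != grid shape {self.grid.shape}")
        object.__setattr__(self, "voxels", v.astype(bool))

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_cm3(self) -> float:
        return self.count * self.grid.voxel_volume_cm3

    def is_empty(self) -> bool:
        return not self.voxels.any()


def update_death(D: np.ndarray, T_min: np.ndarray, T_lethal: float) -> np.ndarray:
    """Binary lethal-isotherm death update.

    A voxel whose minimum temperature has reached ``T_lethal`` is dead
    (D = 1); death is irreversible, so the update takes the elementwise
    maximum with the previous field and is idempotent for a fixed
    ``T_min``.
    """
    if T_lethal >= 0.0:
        raise ValueError(f"lethal isotherm must be sub-freezing, got {T_lethal} degC")
    D = np.asarray(D, dtype=float)
    T_min = np.asarray(T_min, dtype=float)
    if D.shape != T_min.shape:
        raise ValueError(f"shape mismatch: D {D.shape} vs T_min {T_min.shape}")
    return np.maximum(D, np.where(T_min <= T_lethal, 1.0, 0.0))


def extract_zone(
    field: np.ndarray,
    grid: VoxelGrid,
    threshold: float,
    sense: str = "le",
    label: str = "simulated",
) -> AblationMask:
    """Threshold a scalar field into a binary mask.

    ``sense='le'`` keeps voxels with value <= threshold (isotherm
    regions of a temperature field); ``'ge'`` keeps >= (death field).
    """
    field = np.asarray(field, dtype=float)
    if not np.all(np.isfinite(field)):
        raise ValueError("field contains non-finite values")
    if sense in ("le", "<="):
        voxels = field <= threshold
    elif sense in ("ge", ">="):
        voxels = field >= threshold
    else:
        raise ValueError(f"sense must be 'le' or 'ge', got {sense!r}")
    return AblationMask(grid=grid, voxels=voxels, label=label)


def tumor_coverage(zone: AblationMask, tumor: AblationMask) -> float:
    """Fraction of the tumor volume covered by the (simulated) zone."""
    if not zone.grid.same_geometry(tumor.grid):
        raise ValueError("zone and tumor masks live on different grids")
    n_tumor = tumor.count
    if n_tumor == 0:
        raise ValueError("tumor mask is empty")
    return float(np.logical_and(zone.voxels, tumor.voxels).sum()) / n_tumor


def boundary_voxels(mask: AblationMask) -> np.ndarray:
    """Boolean field of face-boundary (6-connectivity) voxels.

    A mask voxel is boundary if at least one of its six face neighbours
    is background; voxels on the array edge count as boundary.
    """
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(mask.voxels, structure=struct, border_value=0)
    return mask.voxels & ~interior


# ---------------------------------------------------------------------------
# minimal enclosing sphere (Welzl's algorithm on convex-hull vertices)

def _sphere_from_support(R: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Smallest sphere with all points of R (|R| <= 4) on its boundary."""
    if not R:
        return np.zeros(3), -1.0
    p0 = R[0]
    if len(R) == 1:
        return p0.copy(), 0.0
    A = np.array([p - p0 for p in R[1:]], dtype=float)
    b = 0.5 * np.einsum("ij,ij->i", A, A)
    # least-norm solution keeps the centre in the affine hull of R
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = p0 + sol
    return center, float(np.linalg.norm(center - p0))


def _welzl(P: list[np.ndarray], R: list[np.ndarray]) -> tuple[np.ndarray, float]:
    if not P or len(R) == 4:
        return _sphere_from_support(R)
    p = P[-1]
    center, r = _welzl(P[:-1], R)
    if r >= 0 and np.linalg.norm(p - center) <= r * (1 + 1e-12) + 1e-12:
        return center, r
    return _welzl(P[:-1], R + [p])


def minimal_enclosing_sphere(points_mm: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact smallest sphere enclosing the points; returns (centre, radius) mm.

    Points are reduced to their convex-hull vertices first (the optimum
    is supported there), then Welzl's randomised incremental algorithm
    runs on the reduced set.
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("no points given")
    if pts.shape[0] > 4:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) sets: use all points
    order = np.random.default_rng(0).permutation(len(pts))
    P = [pts[i] for i in order]
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 4 * len(P) + 100))
    try:
        center, r = _welzl(P, [])
    finally:
        sys.setrecursionlimit(old_limit)
    return center, max(r, 0.0)


def circumscribing_sphere_diameter(mask: AblationMask) -> float:
    """Diameter (cm) of the minimal sphere enclosing all mask voxel centres."""
    if mask.is_empty():
        raise ValueError("cannot circumscribe an empty mask")
    points = mask.grid.voxel_centers_mm(mask.voxels)
    _, radius_mm = minimal_enclosing_sphere(points)
    return 2.0 * radius_mm / 10.0
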