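"""Regular 3D voxel grids with physical (mm) spacing.

All world coordinates are in millimetres, axis-aligned with the voxel
axes, with the centre of voxel index (0, 0, 0) at ``origin_mm`` and
0-based voxel indexing.  Scalar fields (temperature, dead fraction,
heat source) are plain ``numpy`` arrays whose shape equals
``grid.shape``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid"]


@dataclass(frozen=True)
class VoxelGrid:
    """Regular axis-aligned voxel grid.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z).  Each component must be >= 3
        so a 7-point Laplacian stencil has interior room.
    spacing_mm
        Voxel edge lengths in mm, all > 0.
    origin_mm
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing_mm)
        origin = tuple(float(o) for o in self.origin_mm)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("shape, spacing_mm and origin_mm must be triples")
        if any(n < 3 for n in shape):
            raise ValueError(f"grid shape must be >= 3 per axis, got {shape}")
        if any(not np.isfinite(s) or s <= 0 for s in spacing):
            raise ValueError(f"spacings must be positive, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", origin)

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (mm) of voxel centres."""
        return tuple(
            o + s * np.arange(n)
            for n, s, o in zip(self.shape, self.spacing_mm, self.origin_mm)
        )

    def coordinate_fields(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-coordinate (mm) arrays X, Y, Z of shape ``self.shape``."""
        ax, ay, az = self.axes_mm()
        return np.meshgrid(ax, ay, az, indexing="ij")

    def voxel_centers_mm(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n, 3) world coordinates of voxel centres, optionally masked."""
        X, Y, Z = self.coordinate_fields()
        if mask is None:
            return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        return np.column_stack([X[mask], Y[mask], Z[mask]])

    def world_to_index(self, point_mm) -> np.ndarray:
        """Fractional voxel index of a world point."""
        p = np.asarray(point_mm, dtype=float)
        return (p - np.array(self.origin_mm)) / np.array(self.spacing_mm)

    def contains_point(self, point_mm) -> bool:
        """True if the world point lies within the voxel-centre bounding box."""
        idx = self.world_to_index(point_mm)
        return bool(np.all(idx >= 0) and np.all(idx <= np.array(self.shape) - 1))

    def zeros(self, dtype=float) -> np.ndarray:
        return np.zeros(self.shape, dtype=dtype)

    def full(self, value: float, dtype=float) -> np.ndarray:
        return np.full(self.shape, value, dtype=dtype)

    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (diagonal, no rotation)."""
        A = np.eye(4)
        A[0, 0], A[1, 1], A[2, 2] = self.spacing_mm
        A[:3, 3] = self.origin_mm
        return A

    @classmethod
    def from_affine(cls, shape, affine: np.ndarray) -> "VoxelGrid":
        """Build a grid from a diagonal NIfTI-style affine.

        Off-diagonal (rotation/shear) terms must be zero; negative
        diagonal scales are folded into the spacing sign-free with the
        origin kept as given (masks are treated in their native axes).
        """
        A = np.asarray(affine, dtype=float)
        R = A[:3, :3]
        off = R - np.diag(np.diag(R))
        if not np.allclose(off, 0.0, atol=1e-6):
            raise ValueError("only axis-aligned (diagonal) affines are supported")
        spacing = tuple(float(abs(R[i, i])) for i in range(3))
        origin = tuple(float(A[i, 3]) for i in range(3))
        return cls(tuple(int(n) for n in shape), spacing, origin)

    def same_geometry(self, other: "VoxelGrid", tol_mm: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=tol_mm)
            and np.allclose(self.origin_mm, other.origin_mm, atol=tol_mm)
        )
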