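"""Synthetic phantoms: ellipsoidal kidney/tumor masks, exact-overlap mask
pairs, and complete simulation test cases.

Every generator is seed-deterministic: identical arguments and seed give
identical masks, so fixtures never need to be stored on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grid import VoxelGrid
from .needles import Needle, NeedlePlan, write_plan
from .zones import AblationMask

__all__ = [
    "PhantomSpec",
    "make_ellipsoid_mask",
    "make_overlap_pair",
    "make_case_fixture",
    "default_phantom_spec",
]

log = logging.getLogger(__name__)

#: clinical inclusion bound: renal tumours up to 4.5 cm in diameter
MAX_TUMOR_DIAMETER_MM = 45.0


@dataclass(frozen=True)
class PhantomSpec:
    """Ellipsoidal kidney + tumour phantom description."""

    grid: VoxelGrid
    kidney_center_mm: tuple[float, float, float]
    kidney_semi_axes_mm: tuple[float, float, float]
    tumor_center_mm: tuple[float, float, float]
    tumor_semi_axes_mm: tuple[float, float, float]
    seed: int = 0

    def __post_init__(self) -> None:
        for axes in (self.kidney_semi_axes_mm, self.tumor_semi_axes_mm):
            if any(a <= 0 for a in axes):
                raise ValueError(f"semi-axes must be positive, got {axes}")
        if 2.0 * max(self.tumor_semi_axes_mm) > MAX_TUMOR_DIAMETER_MM:
            raise ValueError(
                f"tumour diameter exceeds {MAX_TUMOR_DIAMETER_MM} mm "
                f"(semi-axes {self.tumor_semi_axes_mm})"
            )


def make_ellipsoid_mask(
    grid: VoxelGrid, center_mm, semi_axes_mm, label: str = "tumor"
) -> AblationMask:
    """Voxelise an axis-aligned ellipsoid.

    A voxel is included iff its centre satisfies the ellipsoid
    inequality; a sub-voxel ellipsoid may legitimately produce an empty
    mask.
    """
    c = np.asarray(center_mm, dtype=float)
    ax = np.asarray(semi_axes_mm, dtype=float)
    if ax.shape != (3,) or np.any(ax <= 0) or not np.all(np.isfinite(ax)):
        raise ValueError(f"degenerate semi-axes {semi_axes_mm}")
    X, Y, Z = grid.coordinate_fields()
    q = ((X - c[0]) / ax[0]) ** 2 + ((Y - c[1]) / ax[1]) ** 2 + ((Z - c[2]) / ax[2]) ** 2
    return AblationMask(grid=grid, voxels=q <= 1.0, label=label)


def _digital_ball(grid: VoxelGrid, center_mm, n_voxels: int) -> np.ndarray:
    """Boolean mask of exactly the ``n_voxels`` voxel centres nearest to
    ``center_mm`` (deterministic flat-index tie-break)."""
    if n_voxels == 0:
        return grid.zeros(dtype=bool)
    X, Y, Z = grid.coordinate_fields()
    c = np.asarray(center_mm, dtype=float)
    d2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
    flat = d2.ravel()
    order = np.lexsort((np.arange(flat.size), flat))
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:n_voxels]] = True
    return mask.reshape(grid.shape)


def _equivalent_radius_mm(n_voxels: int, voxel_volume_mm3: float) -> float:
    return (3.0 * n_voxels * voxel_volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)


def make_overlap_pair(
    grid: VoxelGrid,
    vol_S_cm3: float,
    vol_Sigma_cm3: float,
    vol_overlap_cm3: float,
    seed: int = 0,
) -> tuple[AblationMask, AblationMask]:
    """Construct masks S and Sigma with prescribed volumes and overlap.

    The pair is assembled from three pairwise-disjoint digital balls: an
    overlap core shared by both masks and one appendage per mask making
    up the remaining volume.  Ball voxel counts are exact, so measured
    volumes and overlap match the request to within half a voxel
    (rounding of the requested volume to whole voxels).

    Raises if the request is inherently inconsistent or the three balls
    cannot be placed disjointly inside the grid.
    """
    vv = grid.voxel_volume_mm3
    n_S = int(round(vol_S_cm3 * 1000.0 / vv))
    n_Sig = int(round(vol_Sigma_cm3 * 1000.0 / vv))
    n_ov = int(round(vol_overlap_cm3 * 1000.0 / vv))
    if n_S < 1 or n_Sig < 1:
        raise ValueError("each mask must round to at least one voxel")
    if not (0 <= n_ov <= min(n_S, n_Sig)):
        raise ValueError(
            f"requested overlap ({vol_overlap_cm3} cm3) exceeds a mask volume"
        )
    counts = (n_S - n_ov, n_ov, n_Sig - n_ov)  # S-only, core, Sigma-only

    pad = 2.0 * max(grid.spacing_mm)
    radii = [_equivalent_radius_mm(max(n, 1), vv) + pad for n in counts]
    extent = [s * (n - 1) for n, s in zip(grid.shape, grid.spacing_mm)]
    longest = int(np.argmax(extent))
    needed = 2.0 * sum(radii)
    if needed > extent[longest]:
        raise ValueError(
            f"request infeasible on this grid: balls need {needed:.0f} mm "
            f"along an axis but the grid spans {extent[longest]:.0f} mm"
        )
    rng = np.random.default_rng(seed)
    slack = extent[longest] - needed
    margin = rng.uniform(0.0, min(slack, pad))
    centers = []
    x = margin
    for r in radii:
        x += r
        c = [grid.origin_mm[i] + 0.5 * extent[i] for i in range(3)]
        c[longest] = grid.origin_mm[longest] + x
        centers.append(tuple(c))
        x += r

    balls = [_digital_ball(grid, c, n) for c, n in zip(centers, counts)]
    for i in range(3):
        for j in range(i + 1, 3):
            if np.logical_and(balls[i], balls[j]).any():
                raise RuntimeError("overlap-pair construction produced touching balls")
    S = AblationMask(grid=grid, voxels=balls[0] | balls[1], label="reference")
    Sigma = AblationMask(grid=grid, voxels=balls[1] | balls[2], label="simulated")
    return S, Sigma


def default_phantom_spec(grid: VoxelGrid | None = None, seed: int = 0) -> PhantomSpec:
    """Desk-scale default: a 96 mm cube at 1 mm holding kidney + 24 mm tumour."""
    grid = grid or VoxelGrid(shape=(96, 96, 96), spacing_mm=(1.0, 1.0, 1.0))
    cx = [grid.origin_mm[i] + 0.5 * grid.spacing_mm[i] * (grid.shape[i] - 1)
          for i in range(3)]
    return PhantomSpec(
        grid=grid,
        kidney_center_mm=tuple(cx),
        kidney_semi_axes_mm=(45.0, 28.0, 28.0),
        tumor_center_mm=(cx[0] + 17.0, cx[1], cx[2]),
        tumor_semi_axes_mm=(12.0, 10.0, 10.0),
        seed=seed,
    )


def _default_plan(spec: PhantomSpec, n_needles: int) -> NeedlePlan:
    """Parallel needles through the tumour centroid, tips inside the tumour."""
    if not (2 <= n_needles <= 4):
        raise ValueError("default plans use 2-4 needles")
    rng = np.random.default_rng(spec.seed)
    c = np.asarray(spec.tumor_center_mm)
    a = np.asarray(spec.tumor_semi_axes_mm)
    # offsets on a ring in the x-y plane, well inside the tumour cross-section
    ring = 0.45 * min(a[0], a[1])
    phase = rng.uniform(0.0, 2.0 * np.pi)
    needles = []
    for i in range(n_needles):
        angle = phase + 2.0 * np.pi * i / n_needles
        tip = (
            c[0] + ring * np.cos(angle),
            c[1] + ring * np.sin(angle),
            c[2] + 0.3 * a[2],
        )
        needles.append(
            Needle(type="IceRod", tip_mm=tip, direction=(0.0, 0.0, 1.0),
                   power_fraction=1.0)
        )
    return NeedlePlan(tuple(needles))


def make_case_fixture(
    spec: PhantomSpec,
    needles: NeedlePlan | None = None,
    out_dir: str | Path | None = None,
    n_needles: int = 3,
) -> dict:
    """Build a full test case: kidney/tumor masks plus a needle plan.

    Returns a dict with keys ``kidney``, ``tumor`` (AblationMask) and
    ``plan`` (NeedlePlan).  With ``out_dir``, writes ``kidney.nii``,
    ``tumor.nii`` and ``plan.tsv`` there.  Needles that miss the tumour
    entirely are logged as a warning, not an error.
    """
    kidney = make_ellipsoid_mask(
        spec.grid, spec.kidney_center_mm, spec.kidney_semi_axes_mm, label="kidney"
    )
    tumor = make_ellipsoid_mask(
        spec.grid, spec.tumor_center_mm, spec.tumor_semi_axes_mm, label="tumor"
    )
    if np.any(tumor.voxels & ~kidney.voxels):
        raise ValueError("voxelised tumour is not contained in the kidney")
    plan = needles or _default_plan(spec, n_needles)
    for i, needle in enumerate(plan.needles):
        idx = np.rint(spec.grid.world_to_index(needle.tip_mm)).astype(int)
        inside = (
            np.all(idx >= 0)
            and np.all(idx < np.array(spec.grid.shape))
            and tumor.voxels[tuple(idx)]
        )
        if not inside:
            log.warning("needle %d tip %s misses the tumour", i, needle.tip_mm)
    bundle = {"kidney": kidney, "tumor": tumor, "plan": plan}
    if out_dir is not None:
        from .io import write_mask

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_mask(kidney, out / "kidney.nii")
        write_mask(tumor, out / "tumor.nii")
        write_plan(plan, out / "plan.tsv")
    return bundle
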