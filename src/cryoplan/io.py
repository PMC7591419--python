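"""NIfTI mask IO and the end-to-end simulate -> extract -> validate pipeline.

World frame convention (asserted in every header written): millimetres,
axes aligned with the voxel axes, origin at the centre of voxel
(0, 0, 0), 0-based indexing, diagonal affine.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .bioheat import run_protocol
from .config import Config, load_config
from .grid import VoxelGrid
from .metrics import ValidationResult, metrics_from_masks
from .needles import NeedlePlan, read_plan
from .zones import (
    AblationMask,
    circumscribing_sphere_diameter,
    extract_zone,
    tumor_coverage,
)

__all__ = ["read_mask", "write_mask", "write_field", "CaseBundle", "run_case"]

log = logging.getLogger(__name__)


def write_field(field: np.ndarray, grid: VoxelGrid, path: str | Path) -> None:
    """Write a scalar field (temperature, dead fraction) as NIfTI."""
    img = nib.Nifti1Image(np.asarray(field, dtype=np.float32), grid.affine())
    nib.save(img, str(path))


def write_mask(mask: AblationMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.grid.affine())
    nib.save(img, str(path))


def read_mask(path: str | Path, label: str = "reference") -> AblationMask:
    """Read a binary NIfTI mask; any nonzero voxel value maps to True."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got shape {data.shape}")
    grid = VoxelGrid.from_affine(data.shape, img.affine)
    return AblationMask(grid=grid, voxels=data != 0, label=label)


def read_field(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D field, got shape {data.shape}")
    return data, VoxelGrid.from_affine(data.shape, img.affine)


def _check_bundle_geometry(masks: dict[str, AblationMask]) -> VoxelGrid:
    names = list(masks)
    ref_name, ref = names[0], masks[names[0]]
    for name in names[1:]:
        g = masks[name].grid
        if not ref.grid.same_geometry(g):
            raise ValueError(
                f"mask geometry mismatch: {ref_name} has shape={ref.grid.shape} "
                f"spacing={ref.grid.spacing_mm} origin={ref.grid.origin_mm} but "
                f"{name} has shape={g.shape} spacing={g.spacing_mm} "
                f"origin={g.origin_mm}"
            )
    return ref.grid


@dataclass(frozen=True)
class CaseBundle:
    """File paths making up one validation case."""

    plan: Path
    reference: Path | None = None
    tumor: Path | None = None
    kidney: Path | None = None
    config: Path | None = None
    out_dir: Path = Path("cryoplan-out")

    def load_masks(self) -> dict[str, AblationMask]:
        masks: dict[str, AblationMask] = {}
        for name, path in (
            ("reference", self.reference),
            ("tumor", self.tumor),
            ("kidney", self.kidney),
        ):
            if path is not None:
                masks[name] = read_mask(path, label=name)
        return masks


def run_case(bundle: CaseBundle, save_fields: bool = False) -> dict:
    """Run the full pipeline for one case.

    Simulates the freeze-thaw protocol with the plan's needle
    coordinates on the case grid, extracts the simulated ablation zone
    Sigma (lethal isotherm of the minimum-temperature history) and the
    ice ball (0 degC isotherm), validates Sigma against the reference
    zone S when given, and writes a JSON report plus the Sigma mask.

    Returns the report dict.  Every number in the report can be
    recomputed from the masks written next to it.
    """
    cfg: Config = load_config(bundle.config)
    masks = bundle.load_masks()
    grid = _check_bundle_geometry(masks) if masks else cfg.grid
    plan: NeedlePlan = read_plan(bundle.plan)

    log.info("simulating %d-needle protocol on grid %s", len(plan), grid.shape)
    state, D = run_protocol(grid, plan, cfg.protocol, cfg.tissue, controls=cfg.solver)

    sigma = extract_zone(D, grid, 1.0, sense="ge", label="simulated")
    iceball = extract_zone(state.T_min, grid, 0.0, sense="le", label="iceball")

    out = Path(bundle.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_mask(sigma, out / "sigma.nii")
    write_mask(iceball, out / "iceball.nii")
    if save_fields:
        write_field(state.T, grid, out / "temperature.nii")
        write_field(state.T_min, grid, out / "temperature_min.nii")
        write_field(D, grid, out / "dead_fraction.nii")

    report: dict = {
        "grid": {
            "shape": list(grid.shape),
            "spacing_mm": list(grid.spacing_mm),
            "origin_mm": list(grid.origin_mm),
        },
        "n_needles": len(plan),
        "protocol_duration_s": cfg.protocol.total_duration_s,
        "vol_sigma_cm3": sigma.volume_cm3,
        "vol_iceball_cm3": iceball.volume_cm3,
    }
    if not sigma.is_empty():
        report["sigma_circumsphere_diameter_cm"] = circumscribing_sphere_diameter(sigma)
    if "tumor" in masks:
        report["tumor_coverage"] = tumor_coverage(sigma, masks["tumor"])
    if "reference" in masks:
        S = masks["reference"]
        result: ValidationResult = metrics_from_masks(S, sigma)
        report["validation"] = result.to_dict()
        report["s_circumsphere_diameter_cm"] = circumscribing_sphere_diameter(S)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    log.info("report written to %s", out / "report.json")
    return report
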