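"""Configuration loading.

A single YAML file fully specifies the tissue properties, the solver and
probe controls, the freeze-thaw protocol, and the default simulation
grid.  The packaged default lives in ``cryoplan/data/default_config.yaml``;
user files override it section by section (shallow merge per section).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .bioheat import SolverControls, TissueProperties
from .grid import VoxelGrid
from .protocol import Protocol, default_protocol

__all__ = ["Config", "load_config", "default_config_text"]


@dataclass(frozen=True)
class Config:
    tissue: TissueProperties
    solver: SolverControls
    protocol: Protocol
    grid: VoxelGrid
    raw: dict


def default_config_text() -> str:
    return (resources.files("cryoplan") / "data" / "default_config.yaml").read_text()


def _build(raw: dict) -> Config:
    tissue = TissueProperties(**raw["tissue"])
    solver = SolverControls(**raw["solver"])
    p = raw["protocol"]
    protocol = default_protocol(
        n_cycles=int(p["cycles"]),
        freeze_s=float(p["freeze_s"]),
        passive_thaw_s=float(p["passive_thaw_s"]),
        active_thaw_s=float(p["active_thaw_s"]),
    )
    g = raw["grid"]
    grid = VoxelGrid(
        shape=tuple(g["shape"]),
        spacing_mm=tuple(g["spacing_mm"]),
        origin_mm=tuple(g.get("origin_mm", (0.0, 0.0, 0.0))),
    )
    return Config(tissue=tissue, solver=solver, protocol=protocol, grid=grid, raw=raw)


def load_config(path: str | Path | None = None) -> Config:
    """Load a configuration file, falling back to the packaged default.

    A user file only needs the keys it changes; missing keys inside each
    section come from the default.
    """
    raw = yaml.safe_load(default_config_text())
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for section, values in user.items():
            if section in raw and isinstance(values, dict):
                raw[section] = {**raw[section], **values}
            else:
                raw[section] = values
    return _build(raw)
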