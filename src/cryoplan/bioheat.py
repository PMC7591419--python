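"""Pennes bioheat solver with freezing phase change and perfusion norming.

The temperature field obeys a modified Pennes equation

    C_eff(T) dT/dt = div( k_eff(T) grad T ) + w_p + Q

where ``C_eff`` is the apparent volumetric heat capacity (latent heat of
freezing spread over a mushy zone between the solidus and liquidus
temperatures), ``k_eff`` the temperature-dependent conductivity,

    w_p = (1 - D) * omega * rho_b * c_b * (T_body - T)

the blood-perfusion source normed by the local dead-cell fraction ``D``
(dead tissue is no longer perfused; fully frozen voxels carry no
perfusion either), and ``Q`` an optional instrument heat-flux density.

Time stepping is explicit forward Euler in *enthalpy* form: the update
advances the volumetric enthalpy h(T) by the flux divergence and
sources, then inverts the piecewise enthalpy-temperature relation.
With zero-flux boundaries and no sources this conserves total enthalpy
to round-off even when voxels cross the mushy zone, which the naive
``C_eff * dT`` form does not.  Cryoprobes enter as interior Dirichlet
voxels (fixed-temperature cylinders).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .grid import VoxelGrid
from .needles import NeedlePlan, rasterize_plan
from .protocol import Phase, Protocol

__all__ = [
    "TissueProperties",
    "ThermalState",
    "SolverControls",
    "effective_heat_capacity",
    "effective_conductivity",
    "enthalpy_from_temperature",
    "temperature_from_enthalpy",
    "perfusion_term",
    "stable_dt_bound",
    "step_temperature",
    "run_protocol",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TissueProperties:
    """Thermal and perfusion properties of (renal) tissue, SI units.

    The mushy zone ``[T_solidus, T_liquidus]`` is the temperature
    interval over which the latent heat of freezing is released; it must
    satisfy ``T_solidus < T_liquidus <= 0`` degC.
    """

    rho_tissue: float  # kg/m^3
    c_unfrozen: float  # J/(kg K)
    c_frozen: float  # J/(kg K)
    k_unfrozen: float  # W/(m K)
    k_frozen: float  # W/(m K)
    latent_heat: float  # J/kg
    T_liquidus: float  # degC
    T_solidus: float  # degC
    omega_perfusion: float  # 1/s
    rho_blood: float  # kg/m^3
    c_blood: float  # J/(kg K)
    T_body: float = 37.0  # degC

    def __post_init__(self) -> None:
        positive = {
            "rho_tissue": self.rho_tissue,
            "c_unfrozen": self.c_unfrozen,
            "c_frozen": self.c_frozen,
            "k_unfrozen": self.k_unfrozen,
            "k_frozen": self.k_frozen,
            "latent_heat": self.latent_heat,
            "rho_blood": self.rho_blood,
            "c_blood": self.c_blood,
        }
        for name, v in positive.items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if not (self.T_solidus < self.T_liquidus <= 0.0):
            raise ValueError(
                "mushy zone must satisfy T_solidus < T_liquidus <= 0 degC, "
                f"got [{self.T_solidus}, {self.T_liquidus}]"
            )
        if self.omega_perfusion < 0:
            raise ValueError("omega_perfusion must be >= 0")

    @property
    def mushy_width(self) -> float:
        return self.T_liquidus - self.T_solidus


@dataclass(frozen=True)
class ThermalState:
    """Temperature field plus its running per-voxel minimum.

    ``T_min`` carries the coldest temperature each voxel has seen; the
    lethal-isotherm cell-death model is evaluated against it, since
    cryogenic injury is committed at the minimum temperature reached,
    not at the final instant.
    """

    grid: VoxelGrid
    T: np.ndarray
    T_min: np.ndarray
    t_elapsed: float = 0.0

    def __post_init__(self) -> None:
        if self.T.shape != self.grid.shape or self.T_min.shape != self.grid.shape:
            raise ValueError("temperature fields must match the grid shape")
        if np.any(self.T_min > self.T + 1e-12):
            raise ValueError("T_min must be <= T everywhere")

    @classmethod
    def initial(cls, grid: VoxelGrid, T_body: float) -> "ThermalState":
        T = grid.full(float(T_body))
        return cls(grid=grid, T=T, T_min=T.copy(), t_elapsed=0.0)


@dataclass(frozen=True)
class SolverControls:
    """Explicit-stepper and probe-model controls.

    T_freeze_C is the probe surface temperature at 100% freezing power;
    a needle at power fraction p imposes T_body + p*(T_freeze - T_body).
    Active thaw imposes T_thaw_C.  ``dt_s=None`` selects the automatic
    stable step (``dt_safety`` times the explicit bound).
    """

    T_freeze_C: float = -140.0
    T_thaw_C: float = 20.0
    T_lethal_C: float = -20.0
    dt_s: float | None = None
    dt_safety: float = 0.8

    def __post_init__(self) -> None:
        if not (0 < self.dt_safety <= 1.0):
            raise ValueError("dt_safety must be in (0, 1]")
        if self.dt_s is not None and self.dt_s <= 0:
            raise ValueError("dt_s must be positive")


def _check_finite_temperature(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("temperature contains non-finite values")
    return T


def effective_heat_capacity(T, props: TissueProperties) -> np.ndarray:
    """Apparent volumetric heat capacity C_eff(T) in J/(m^3 K).

    Outside the mushy zone this is rho*c of the respective phase; inside
    it the latent heat is spread uniformly over the zone width and the
    sensible capacity interpolates linearly frozen -> unfrozen
    (apparent-heat-capacity / enthalpy-spreading method).
    """
    T = _check_finite_temperature(T)
    Ts, Tl, W = props.T_solidus, props.T_liquidus, props.mushy_width
    frac = np.clip((T - Ts) / W, 0.0, 1.0)
    c_mix = props.c_frozen + (props.c_unfrozen - props.c_frozen) * frac
    C = props.rho_tissue * (c_mix + props.latent_heat / W)
    C = np.where(T >= Tl, props.rho_tissue * props.c_unfrozen, C)
    C = np.where(T <= Ts, props.rho_tissue * props.c_frozen, C)
    return C if C.ndim else float(C)


def effective_conductivity(T, props: TissueProperties) -> np.ndarray:
    """Thermal conductivity k_eff(T) in W/(m K), linear across the mushy zone."""
    T = _check_finite_temperature(T)
    frac = np.clip((T - props.T_solidus) / props.mushy_width, 0.0, 1.0)
    k = props.k_frozen + (props.k_unfrozen - props.k_frozen) * frac
    return k if k.ndim else float(k)


def enthalpy_from_temperature(T, props: TissueProperties) -> np.ndarray:
    """Volumetric enthalpy h(T) in J/m^3, zero at the solidus temperature.

    Piecewise: linear below the solidus (frozen sensible heat),
    quadratic across the mushy zone (interpolated sensible heat plus
    uniformly released latent heat), linear above the liquidus.  The
    derivative dh/dT equals :func:`effective_heat_capacity` everywhere.
    """
    T = _check_finite_temperature(T)
    rho = props.rho_tissue
    Ts, W = props.T_solidus, props.mushy_width
    cf, cu, L = props.c_frozen, props.c_unfrozen, props.latent_heat
    theta = np.clip(T - Ts, 0.0, W)
    h_mushy = rho * (cf * theta + 0.5 * (cu - cf) * theta**2 / W + L * theta / W)
    h = h_mushy
    h = h + np.where(T < Ts, rho * cf * (T - Ts), 0.0)
    h = h + np.where(T > Ts + W, rho * cu * (T - Ts - W), 0.0)
    return h if h.ndim else float(h)


def temperature_from_enthalpy(h, props: TissueProperties) -> np.ndarray:
    """Invert :func:`enthalpy_from_temperature` (exact piecewise inverse)."""
    h = np.asarray(h, dtype=float)
    rho = props.rho_tissue
    Ts, W = props.T_solidus, props.mushy_width
    cf, cu, L = props.c_frozen, props.c_unfrozen, props.latent_heat
    h_liq = rho * (0.5 * (cf + cu) * W + L)
    # mushy branch: a*theta^2 + b*theta = h, stable root form valid for any sign of a
    a = 0.5 * rho * (cu - cf) / W
    b = rho * (cf + L / W)
    hc = np.clip(h, 0.0, h_liq)
    disc = np.sqrt(b * b + 4.0 * a * hc)
    theta = 2.0 * hc / (b + disc)
    T = Ts + theta
    T = np.where(h < 0.0, Ts + h / (rho * cf), T)
    T = np.where(h > h_liq, Ts + W + (h - h_liq) / (rho * cu), T)
    return T if T.ndim else float(T)


def perfusion_term(T, D, props: TissueProperties) -> np.ndarray:
    """Dead-fraction-normed Pennes perfusion source, W/m^3.

    ``(1 - D) * omega * rho_blood * c_blood * (T_body - T)``, forced to
    zero wherever the tissue is fully frozen (T <= T_solidus): frozen
    tissue carries no blood flow regardless of the death field.
    """
    T = np.asarray(T, dtype=float)
    D = np.asarray(D, dtype=float)
    if T.shape != D.shape:
        raise ValueError(f"shape mismatch: T {T.shape} vs D {D.shape}")
    w = (1.0 - D) * props.omega_perfusion * props.rho_blood * props.c_blood
    q = w * (props.T_body - T)
    return np.where(T <= props.T_solidus, 0.0, q)


def _inv_dx2_m(grid: VoxelGrid) -> tuple[float, float, float]:
    return tuple(1.0 / (s * 1e-3) ** 2 for s in grid.spacing_mm)


def _flux_divergence(T: np.ndarray, k: np.ndarray, inv_dx2) -> np.ndarray:
    """div(k grad T) on a 7-point stencil, zero-flux outer boundary, W/m^3.

    Face conductivities are arithmetic means of the adjacent voxels;
    the antisymmetric face-flux accumulation makes the operator exactly
    conservative under insulated boundaries.
    """
    div = np.zeros_like(T)
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        k_face = 0.5 * (k[lo] + k[hi])
        g = k_face * (T[hi] - T[lo]) * inv_dx2[axis]
        div[lo] += g
        div[hi] -= g
    return div


def stable_dt_bound(T, props: TissueProperties, grid: VoxelGrid) -> float:
    """Per-voxel explicit stability bound min C_eff / (2 k_eff sum 1/dx^2)."""
    C = np.asarray(effective_heat_capacity(T, props), dtype=float)
    k = np.asarray(effective_conductivity(T, props), dtype=float)
    S = sum(_inv_dx2_m(grid))
    return float(np.min(C / (2.0 * k * S)))


def conservative_dt_bound(props: TissueProperties, grid: VoxelGrid) -> float:
    """Temperature-independent stability bound (worst case over all T)."""
    C_min = props.rho_tissue * min(props.c_frozen, props.c_unfrozen)
    k_max = max(props.k_frozen, props.k_unfrozen)
    S = sum(_inv_dx2_m(grid))
    return C_min / (2.0 * k_max * S)


def step_temperature(
    state: ThermalState,
    D: np.ndarray,
    Q: np.ndarray | None,
    props: TissueProperties,
    dt: float,
    *,
    dirichlet_mask: np.ndarray | None = None,
    dirichlet_values: np.ndarray | float | None = None,
    check_stability: bool = True,
) -> ThermalState:
    """Advance the bioheat equation one explicit step of length ``dt`` s.

    ``dirichlet_mask``/``dirichlet_values`` pin interior voxels (probe
    cylinders, or analytic boundary shells in benchmarks) to fixed
    temperatures after the update.  Raises if ``dt`` exceeds the
    explicit stability bound, naming the maximal admissible step.
    """
    grid = state.grid
    T = state.T
    if D.shape != T.shape:
        raise ValueError("dead-fraction field shape mismatch")
    if check_stability:
        bound = stable_dt_bound(T, props, grid)
        if dt > bound * (1.0 + 1e-12):
            raise ValueError(
                f"dt={dt:g} s violates the explicit stability bound; "
                f"maximal admissible dt is {bound:g} s"
            )
    k = np.asarray(effective_conductivity(T, props), dtype=float)
    rhs = _flux_divergence(T, k, _inv_dx2_m(grid))
    rhs = rhs + perfusion_term(T, D, props)
    if Q is not None:
        rhs = rhs + Q
    h = enthalpy_from_temperature(T, props) + dt * rhs
    T_new = temperature_from_enthalpy(h, props)
    if dirichlet_mask is not None:
        vals = np.asarray(dirichlet_values, dtype=float)
        T_new[dirichlet_mask] = vals[dirichlet_mask] if vals.shape == T_new.shape else vals
    T_min_new = np.minimum(state.T_min, T_new)
    return ThermalState(grid=grid, T=T_new, T_min=T_min_new, t_elapsed=state.t_elapsed + dt)


def _phase_dirichlet(
    phase: Phase,
    plan: NeedlePlan,
    probe_masks: list[np.ndarray],
    props: TissueProperties,
    controls: SolverControls,
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Probe Dirichlet mask and per-voxel temperatures for one phase."""
    if phase.mode == "passive_thaw":
        return None, None
    union = np.zeros(probe_masks[0].shape, dtype=bool)
    values = np.zeros(probe_masks[0].shape, dtype=float)
    for needle, mask in zip(plan.needles, probe_masks):
        if phase.mode == "freeze":
            T_probe = props.T_body + needle.power_fraction * (
                controls.T_freeze_C - props.T_body
            )
        else:  # active_thaw
            T_probe = controls.T_thaw_C
        values[mask] = T_probe
        union |= mask
    return union, values


def run_protocol(
    grid: VoxelGrid,
    needles: NeedlePlan,
    protocol: Protocol,
    props: TissueProperties,
    *,
    controls: SolverControls | None = None,
    observer=None,
) -> tuple[ThermalState, np.ndarray]:
    """Simulate a full freeze-thaw protocol; return final state and death field.

    The death field is the binary lethal-isotherm model evaluated
    against the running minimum temperature after every step.  A
    protocol with no phases returns the untouched body-temperature
    state (death field all zero).

    ``observer(state, D, phase, step)``, when given, is called after
    every step; tests use it to track ice-ball growth.
    """
    from .zones import update_death

    controls = controls or SolverControls()
    for needle in needles.needles:
        if not grid.contains_point(needle.tip_mm):
            raise ValueError(
                f"needle tip {needle.tip_mm} lies outside the grid "
                f"(shape {grid.shape}, spacing {grid.spacing_mm} mm)"
            )
    protocol.validate()

    probe_masks = rasterize_plan(grid, needles)
    state = ThermalState.initial(grid, props.T_body)
    D = grid.zeros()

    for i_phase, phase in enumerate(protocol.phases):
        mask, values = _phase_dirichlet(phase, needles, probe_masks, props, controls)
        if mask is not None:
            # impose the probe condition at phase start so the first step
            # already sees the boundary temperature
            T = state.T.copy()
            T[mask] = values[mask]
            state = ThermalState(
                grid=grid,
                T=T,
                T_min=np.minimum(state.T_min, T),
                t_elapsed=state.t_elapsed,
            )
            D = update_death(D, state.T_min, controls.T_lethal_C)
        dt_cap = controls.dt_s or controls.dt_safety * conservative_dt_bound(props, grid)
        n_steps = max(1, math.ceil(phase.duration_s / dt_cap))
        dt = phase.duration_s / n_steps
        log.info(
            "phase %d/%d %s: %.0f s in %d steps (t=%.0f s)",
            i_phase + 1, len(protocol.phases), phase.mode,
            phase.duration_s, n_steps, state.t_elapsed,
        )
        # the automatic dt already satisfies the worst-case bound; only a
        # user-supplied fixed dt needs the per-step check
        check = controls.dt_s is not None
        for step in range(n_steps):
            state = step_temperature(
                state, D, None, props, dt,
                dirichlet_mask=mask,
                dirichlet_values=values,
                check_stability=check,
            )
            D = update_death(D, state.T_min, controls.T_lethal_C)
            if observer is not None:
                observer(state, D, phase, step)
    return state, D
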