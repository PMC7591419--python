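# Methods

## Thermal model

The temperature field `T(x, t)` on a regular voxel grid obeys a modified
Pennes bioheat equation

    C_eff(T) ∂T/∂t = ∇·(k_eff(T) ∇T) + (1 − D) ω ρ_b c_b (T_body − T) + Q

with volumetric apparent heat capacity `C_eff`, temperature-dependent
conductivity `k_eff`, blood perfusion rate `ω` (1/s), blood density and
specific heat `ρ_b`, `c_b`, dead-cell fraction `D ∈ [0, 1]`, and an
optional instrument heat-flux density `Q` (W/m³, negative while
freezing). Assumptions:

- homogeneous tissue (one property set for the whole domain);
- perfusion acts as a volumetric heat source proportional to
  `T_body − T`, attenuated linearly by the dead fraction (dead tissue is
  not perfused) and exactly zero in fully frozen voxels
  (`T ≤ T_solidus`): capillaries in ice carry no blood regardless of
  viability;
- the metabolic heat term is neglected (orders of magnitude below the
  probe fluxes at cryogenic gradients);
- the outer boundary is insulated (zero flux). The domain should be
  chosen comfortably larger than the expected ice ball; the grid
  convergence and maximum-principle tests operate in that regime.

### Phase change

Freezing releases the latent heat `L` across a mushy zone
`[T_solidus, T_liquidus]` (defaults −8 °C … −1 °C). The apparent heat
capacity inside the zone is

    C_eff = ρ (c_mix(T) + L / (T_liquidus − T_solidus)),

where `c_mix` interpolates linearly from `c_frozen` at the solidus to
`c_unfrozen` at the liquidus; `k_eff` interpolates the same way. Outside
the zone the pure-phase values apply. The associated volumetric enthalpy
`h(T)` (zero at the solidus) is piecewise linear–quadratic–linear and
`dh/dT = C_eff` everywhere.

### Discretization

7-point finite-difference Laplacian in flux-divergence form with
arithmetic-mean face conductivities, explicit forward Euler in time.
The update is advanced **in enthalpy**: `h ← h + Δt (∇·k∇T + sources)`,
then `T = h⁻¹(h)` through the exact piecewise inverse. Because the face
fluxes are antisymmetric and the boundary is insulated, total enthalpy
is conserved to round-off with sources off — including when voxels cross
the mushy zone, where a naive `C_eff ΔT` update would drift by O(Δt).
The quadratic mushy branch is inverted with the numerically stable root
form `θ = 2h / (b + √(b² + 4ah))`, valid for either sign of
`c_unfrozen − c_frozen` and in the limit `a → 0`.

The explicit stability bound is evaluated per voxel as
`Δt ≤ C_eff / (2 k_eff (1/Δx² + 1/Δy² + 1/Δz²))`; `step_temperature`
rejects a violating step naming the admissible maximum. Protocol runs
use the temperature-independent worst case
`ρ min(c) / (2 max(k) Σ 1/Δx²)` times a safety factor (default 0.8) and
divide each phase into equal steps, so no per-step check is needed.

### Probes

Needles are active-tip cylinders rasterized as interior Dirichlet
voxels: a voxel belongs to a probe if its centre lies within the shaft
radius (default 0.735 mm, 17 G) of the tip-to-base segment. At coarse
spacings, where the thin cylinder may miss every voxel centre, the
nearest voxel to each segment sample is taken instead so a probe is
never invisible. During freezing a probe at power fraction `p` is held
at `T_body + p (T_freeze − T_body)` with `T_freeze = −140 °C` by
default — the simplest interpretation of "percentage of maximum freezing
power" that is monotone in `p`. Passive thaw removes the constraint;
active thaw holds probes at `+20 °C`. Two probe types are provided,
differing by active-tip length (15 mm / 25 mm); these geometric defaults
are working values, not vendor datasheet numbers, and are configurable
per needle. Multi-needle synergy needs no special treatment: all probes
share one temperature field, so combined ice balls emerge from the
physics rather than from a union-of-single-probes approximation.

### Cell death and zone extraction

Death is the binary lethal-isotherm model: a voxel is dead once the
running minimum of its temperature reaches `T_lethal` (default −20 °C;
the commonly quoted clinical range is −20 … −40 °C and the default sits
at its conservative end — the parameter is deliberately easy to sweep).
The dead field is stored as a real-valued fraction for forward
compatibility, but this model only produces {0, 1}. Evaluating against
the minimum-temperature history rather than the final field encodes
that cryogenic injury is committed at the coldest instant; it also makes
the simulated zone Σ invariant to anything that happens after the last
freeze. Since `T_lethal < 0`, Σ is always contained in the ice ball
(0 °C isotherm of the same history).

## Validation metrics

DSC, target overlap (TO, also reported as "sensitivity") and positive
predictive value (PPV) are voxel-count ratios; they satisfy the exact
identity `DSC = 2·TO·PPV / (TO + PPV)`, which the tests verify to 1e-12.
The absolute average error (AAE) is the symmetric mean surface distance:
face-boundary voxels (6-connectivity, array edges count as boundary) of
each mask are taken as surface points at their centres, each point
contributes its Euclidean distance to the nearest point of the other
surface, and the mean is weighted by point counts over both directions.
The symmetric form was chosen because a one-sided distance cannot be
symmetric under argument exchange and the metric is meant to compare two
segmentations on an equal footing.

Ratings follow the five-level ordinal scale with lower edges 0.5 / 0.6 /
0.7 / 0.8; the top bin is closed above so a perfect ratio of 1.0 rates
excellent rather than falling off the scale. Stored metric values are
never rounded; rounding (volumes to 2 decimals, DSC sometimes to 1) is a
display concern only.

The minimal enclosing sphere of a mask (reported as a circumscribing
diameter in cm) is computed exactly with Welzl's randomised incremental
algorithm after reducing the voxel centres to their convex-hull
vertices; degenerate (coplanar) point sets skip the hull reduction.

## Phantoms

`make_ellipsoid_mask` voxelises axis-aligned ellipsoids by the
centre-inside rule. `make_overlap_pair` builds a mask pair with
prescribed volumes and overlap from three pairwise-disjoint "digital
balls" — each ball is exactly the n nearest voxel centres to a centre
point (deterministic flat-index tie-break) — so the requested voxel
counts are met exactly and only the rounding of a requested volume to
whole voxels (≤ half a voxel) separates request from measurement. The
three centres are laid out along the longest grid axis with a
two-voxel pad; infeasible requests (balls cannot fit disjointly) raise.
`make_case_fixture` assembles a kidney ellipsoid, a contained tumour
(≤ 45 mm diameter, the clinical inclusion bound), and a 2–4 needle plan
through the tumour centroid. All generation is seed-deterministic.

What the phantoms do **not** emulate: anatomical shape detail,
heterogeneous perfusion (large vessels, collecting system), image
intensities, segmentation error, or needle placement uncertainty.
Passing metric tests on phantoms therefore demonstrates correctness of
the arithmetic and the pipeline, not clinical accuracy of the thermal
model on real kidneys.

## Default parameters

| parameter | default | unit | note |
|---|---|---|---|
| ρ tissue | 1050 | kg/m³ | kidney-scale working value |
| c unfrozen / frozen | 3600 / 1800 | J/(kg·K) | |
| k unfrozen / frozen | 0.52 / 2.0 | W/(m·K) | ice conducts ~4× better |
| latent heat | 250 000 | J/kg | tissue water content < pure water |
| mushy zone | [−8, −1] | °C | standard for biological tissue |
| ω perfusion | 0.004 | 1/s | |
| ρ_b, c_b blood | 1060, 3600 | kg/m³, J/(kg·K) | |
| T_body | 37 | °C | |
| T_freeze / T_thaw | −140 / +20 | °C | probe surface temperatures |
| T_lethal | −20 | °C | lethal isotherm |
| dt_safety | 0.8 | — | fraction of stability bound |

All of these live in `cryoplan/data/default_config.yaml` and are
overridden section-by-section by a user config; none are hard-coded in
the numerical operations. They are literature-scale working defaults
chosen once for plausibility, not fitted values.

## Problem sizes and numerical checks

Desk-scale grids are used throughout: the packaged default simulation
grid is 64³ at 2 mm (a 12.8 cm cube, ample for a ≤ 4.5 cm tumour), the
phantom default is 96³ at 1 mm for mask-level work, and the analytic
conduction benchmark runs on 64³ at 1 mm. At 2 mm the automatic stable
step is ≈ 0.5 s, so a full double freeze–thaw protocol (26 min) takes
about 3100 steps.

Numerical choices worth knowing:

- The solver is verified bitwise against a dense triple-loop oracle on
  an 8³ grid — the vectorised and looped updates perform identical
  floating-point operations in identical order.
- The steady-state benchmark imposes the analytic spherical-conduction
  profile `T(r) = T_body + (T_p − T_body) R/r` on the outer voxel shell
  (a harmonic function satisfies the interior stencil exactly, so the
  discrete fixed point matches the analytic solution up to probe
  rasterization); agreement at half-domain radius is ~1% of the
  temperature scale, tested against a 5% bound.
- Ice-ball volume changes by < 5% when the spacing is halved from 2 mm
  to 1 mm for a fixed spherical-probe scenario (measured ≈ 1–2%).
- In multi-cycle protocols, the instantaneous frozen-voxel count
  (`T < 0`) is *not* strictly monotone at the start of a re-freeze: the
  detached sub-zero rim left by the thaw phases keeps collapsing for a
  short transient (first few percent of the phase) while the probes
  re-freeze their own neighbourhood. The monotonicity tests assert
  strict growth for the first freeze and growth after this transient
  for re-freezes. The *ever-frozen* region (via the minimum-temperature
  history) and the death field are monotone throughout, by construction.
- Degenerate inputs are defined, not crashes: sub-voxel ellipsoids may
  produce empty masks; an empty protocol returns the body-temperature
  state; empty masks are rejected by every metric with a specific error.

## Known limitations

- Explicit stepping only; very fine grids (≤ 0.5 mm) make protocol-scale
  runs slow. An implicit scheme is out of scope.
- Binary isotherm death — no Arrhenius kinetics, no freeze-rate or
  double-freeze sensitisation effects, although the double cycle does
  deepen the minimum-temperature history.
- The power-fraction → probe-temperature map is a linear modelling
  choice, not device physics.
- Homogeneous tissue: no large-vessel heat sinks, which clinically cause
  local under-freezing.
- Masks must share one axis-aligned grid; no resampling or registration
  is provided.
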