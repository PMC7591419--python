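# Default cryoablation planning configuration.
#
# Tissue constants are literature-scale kidney values chosen as working
# defaults; they are deliberately configurable and should be reviewed
# against the tissue at hand before clinical-scale use.

tissue:
  rho_tissue: 1050.0       # kg/m^3
  c_unfrozen: 3600.0       # J/(kg K)
  c_frozen: 1800.0         # J/(kg K)
  k_unfrozen: 0.52         # W/(m K)
  k_frozen: 2.0            # W/(m K)
  latent_heat: 250000.0    # J/kg
  T_liquidus: -1.0         # degC, upper edge of the mushy zone
  T_solidus: -8.0          # degC, lower edge of the mushy zone
  omega_perfusion: 0.004   # 1/s
  rho_blood: 1060.0        # kg/m^3
  c_blood: 3600.0          # J/(kg K)
  T_body: 37.0             # degC

solver:
  T_freeze_C: -140.0       # probe surface at 100% freezing power
  T_thaw_C: 20.0           # probe surface during active thaw
  T_lethal_C: -20.0        # lethal isotherm applied to the minimum temperature
  dt_s: null               # null = automatic stable step
  dt_safety: 0.8           # fraction of the explicit stability bound

# Simulation grid used when no input masks fix the geometry.
# 2 mm spacing keeps a full double freeze-thaw protocol at desk scale.
grid:
  shape: [64, 64, 64]
  spacing_mm: [2.0, 2.0, 2.0]
  origin_mm: [0.0, 0.0, 0.0]

# Double freeze-thaw cycle: 10 min freeze, 2 min passive thaw,
# 1 min active thaw, twice.
protocol:
  cycles: 2
  freeze_s: 600.0
  passive_thaw_s: 120.0
  active_thaw_s: 60.0
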