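import numpy as np
import pytest
from hypothesis import settings

from cryoplan import (
    Needle,
    NeedlePlan,
    Phase,
    Protocol,
    SolverControls,
    TissueProperties,
    VoxelGrid,
    load_config,
    run_protocol,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def props() -> TissueProperties:
    """Default kidney tissue properties from the packaged config."""
    return load_config().tissue


@pytest.fixture(scope="session")
def const_props() -> TissueProperties:
    """Constant-property, perfusion-free tissue for analytic benchmarks."""
    return TissueProperties(
        rho_tissue=1050.0, c_unfrozen=3600.0, c_frozen=3600.0,
        k_unfrozen=0.52, k_frozen=0.52, latent_heat=1e-3,
        T_liquidus=-1.0, T_solidus=-8.0, omega_perfusion=0.0,
        rho_blood=1060.0, c_blood=3600.0, T_body=37.0,
    )


@pytest.fixture(scope="session")
def small_sim(props):
    """One centred IceRod, 5 min freeze, 40^3 grid at 2 mm.

    Shared across tests that only need *a* completed simulation
    (ice-ball containment, zone topology, erosion signatures).
    """
    grid = VoxelGrid((40, 40, 40), (2.0, 2.0, 2.0))
    plan = NeedlePlan((
        Needle("IceRod", tip_mm=(39.0, 39.0, 45.0), direction=(0.0, 0.0, 1.0)),
    ))
    protocol = Protocol((Phase("freeze", 300.0),))
    controls = SolverControls()
    state, D = run_protocol(grid, plan, protocol, props, controls=controls)
    return {"grid": grid, "plan": plan, "state": state, "D": D,
            "controls": controls, "protocol": protocol}


def hand_props(**overrides) -> TissueProperties:
    """Round-number properties for hand-computed oracles."""
    base = dict(
        rho_tissue=1000.0, c_unfrozen=4000.0, c_frozen=2000.0,
        k_unfrozen=0.5, k_frozen=2.0, latent_heat=300000.0,
        T_liquidus=-1.0, T_solidus=-8.0, omega_perfusion=0.004,
        rho_blood=1060.0, c_blood=3600.0, T_body=37.0,
    )
    base.update(overrides)
    return TissueProperties(**base)
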