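"""Unit and property tests for the phase-change bioheat solver."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cryoplan import (
    Needle,
    NeedlePlan,
    Phase,
    Protocol,
    SolverControls,
    VoxelGrid,
    run_protocol,
)
from cryoplan.bioheat import (
    ThermalState,
    conservative_dt_bound,
    effective_conductivity,
    effective_heat_capacity,
    enthalpy_from_temperature,
    perfusion_term,
    stable_dt_bound,
    step_temperature,
    temperature_from_enthalpy,
)

from conftest import hand_props
from oracles import brute_force_step


class TestEffectiveHeatCapacity:
    def test_pure_phase_branches(self, props):
        assert effective_heat_capacity(37.0, props) == props.rho_tissue * props.c_unfrozen
        assert effective_heat_capacity(-60.0, props) == props.rho_tissue * props.c_frozen

    def test_mushy_zone_carries_latent_heat(self, props):
        mid = 0.5 * (props.T_solidus + props.T_liquidus)
        c_mix = 0.5 * (props.c_frozen + props.c_unfrozen)
        expected = props.rho_tissue * (c_mix + props.latent_heat / props.mushy_width)
        assert effective_heat_capacity(mid, props) == pytest.approx(expected)

    def test_quadrature_matches_enthalpy_difference(self, props):
        """Integrating C_eff over T must recover the closed-form enthalpy
        change including the latent heat (trapezoid at 0.01 degC)."""
        T = np.arange(-60.0, 37.0 + 1e-9, 0.01)
        integral = np.trapezoid(effective_heat_capacity(T, props), T)
        closed = (
            enthalpy_from_temperature(37.0, props)
            - enthalpy_from_temperature(-60.0, props)
        )
        rho = props.rho_tissue
        by_hand = rho * (
            props.c_frozen * (props.T_solidus - (-60.0))
            + 0.5 * (props.c_frozen + props.c_unfrozen) * props.mushy_width
            + props.latent_heat
            + props.c_unfrozen * (37.0 - props.T_liquidus)
        )
        assert closed == pytest.approx(by_hand, rel=1e-12)
        assert integral == pytest.approx(closed, rel=1e-3)

    def test_rejects_non_finite_temperature(self, props):
        with pytest.raises(ValueError):
            effective_heat_capacity(np.nan, props)


class TestEffectiveConductivity:
    def test_endpoints_and_midpoint(self, props):
        assert effective_conductivity(37.0, props) == props.k_unfrozen
        assert effective_conductivity(-60.0, props) == props.k_frozen
        mid = 0.5 * (props.T_solidus + props.T_liquidus)
        assert effective_conductivity(mid, props) == pytest.approx(
            0.5 * (props.k_frozen + props.k_unfrozen)
        )

    def test_monotone_non_increasing(self, props):
        T = np.linspace(-80.0, 40.0, 1000)
        k = effective_conductivity(T, props)
        assert np.all(np.diff(k) <= 1e-15)


class TestEnthalpy:
    @given(st.floats(min_value=-120.0, max_value=60.0))
    def test_roundtrip_is_exact_inverse(self, T):
        p = hand_props()
        h = enthalpy_from_temperature(T, p)
        assert temperature_from_enthalpy(h, p) == pytest.approx(T, abs=1e-9)

    def test_derivative_is_effective_capacity(self, props):
        # central differences away from the two kinks
        T = np.concatenate([
            np.linspace(-60, props.T_solidus - 0.1, 50),
            np.linspace(props.T_solidus + 0.1, props.T_liquidus - 0.1, 50),
            np.linspace(props.T_liquidus + 0.1, 37, 50),
        ])
        eps = 1e-4
        dh = (
            enthalpy_from_temperature(T + eps, props)
            - enthalpy_from_temperature(T - eps, props)
        ) / (2 * eps)
        assert np.allclose(dh, effective_heat_capacity(T, props), rtol=1e-5)


class TestPerfusion:
    def test_zero_at_body_temperature(self, props):
        T = np.full((4, 4, 4), props.T_body)
        D = np.zeros_like(T)
        assert np.all(perfusion_term(T, D, props) == 0.0)

    def test_dead_tissue_not_perfused(self, props):
        T = np.full((4, 4, 4), 20.0)
        D = np.ones_like(T)
        assert np.all(perfusion_term(T, D, props) == 0.0)

    def test_hand_value(self):
        """Half-dead voxel at 27 degC: 0.5*0.004*1060*3600*10 = 76320 W/m^3."""
        p = hand_props(omega_perfusion=0.004, rho_blood=1060.0, c_blood=3600.0)
        T = np.array([[[27.0]]])
        D = np.array([[[0.5]]])
        assert perfusion_term(T, D, p)[0, 0, 0] == pytest.approx(76320.0)

    def test_no_perfusion_through_frozen_tissue(self, props):
        T = np.full((3, 3, 3), props.T_solidus - 5.0)
        D = np.zeros_like(T)
        assert np.all(perfusion_term(T, D, props) == 0.0)

    def test_shape_mismatch_raises(self, props):
        with pytest.raises(ValueError, match="shape mismatch"):
            perfusion_term(np.zeros((3, 3, 3)), np.zeros((4, 4, 4)), props)


class TestStepTemperature:
    def test_equilibrium_is_exact_fixed_point(self, props):
        grid = VoxelGrid((5, 5, 5), (2.0, 2.0, 2.0))
        state = ThermalState.initial(grid, props.T_body)
        D = grid.zeros()
        new = step_temperature(state, D, None, props, 0.1)
        assert np.array_equal(new.T, state.T)
        assert new.t_elapsed == pytest.approx(0.1)

    def test_two_voxel_heat_flux_matches_hand_step(self):
        """Heat flows hot -> cold with flux k*dT/dx^2 * dt / C (both voxels
        in the unfrozen branch, so the enthalpy update is linear)."""
        p = hand_props(omega_perfusion=0.0)
        grid = VoxelGrid((3, 3, 3), (2.0, 2.0, 2.0))
        T = grid.full(p.T_body)
        T[0, 1, 1] = 39.0  # hot voxel next to a 37.0 voxel
        state = ThermalState(grid=grid, T=T, T_min=T.copy())
        dt = 0.05
        new = step_temperature(state, grid.zeros(), None, p, dt)
        dx2 = (2.0e-3) ** 2
        C = p.rho_tissue * p.c_unfrozen
        flux = p.k_unfrozen * (39.0 - 37.0) / dx2  # W/m^3 into the cold voxel
        assert new.T[1, 1, 1] == pytest.approx(37.0 + dt * flux / C, rel=1e-12)
        assert new.T[0, 1, 1] < 39.0

    def test_stability_violation_names_admissible_dt(self, props):
        grid = VoxelGrid((4, 4, 4), (1.0, 1.0, 1.0))
        state = ThermalState.initial(grid, props.T_body)
        bound = stable_dt_bound(state.T, props, grid)
        with pytest.raises(ValueError, match="maximal admissible dt"):
            step_temperature(state, grid.zeros(), None, props, 2.0 * bound)
        # message carries the numeric bound
        try:
            step_temperature(state, grid.zeros(), None, props, 2.0 * bound)
        except ValueError as err:
            assert f"{bound:g}" in str(err)

    def test_enthalpy_conserved_without_sources(self, props):
        """Insulated boundaries, no perfusion, no probes: total enthalpy is
        conserved to round-off even while voxels cross the mushy zone."""
        from cryoplan.bioheat import TissueProperties

        p = TissueProperties(
            **{**props.__dict__, "omega_perfusion": 0.0}
        )
        grid = VoxelGrid((8, 8, 8), (2.0, 2.0, 2.0))
        rng = np.random.default_rng(7)
        T = rng.uniform(-30.0, 37.0, grid.shape)  # straddles the mushy zone
        state = ThermalState(grid=grid, T=T, T_min=T.copy())
        vol = (2.0e-3) ** 3
        H0 = float(np.sum(enthalpy_from_temperature(state.T, p))) * vol
        dt = 0.5 * stable_dt_bound(state.T, p, grid)
        for _ in range(200):
            state = step_temperature(state, grid.zeros(), None, p, dt,
                                     check_stability=False)
        H1 = float(np.sum(enthalpy_from_temperature(state.T, p))) * vol
        assert H1 == pytest.approx(H0, rel=1e-6)

    def test_matches_brute_force_loop_oracle(self, props):
        """10 steps on an 8^3 grid agree bitwise with a pure-Python
        triple-loop re-implementation of the update."""
        grid = VoxelGrid((8, 8, 8), (2.0, 2.0, 2.0))
        rng = np.random.default_rng(3)
        T = rng.uniform(-40.0, 37.0, grid.shape)
        D = rng.uniform(0.0, 1.0, grid.shape)
        Q = rng.uniform(-5e4, 0.0, grid.shape)
        state = ThermalState(grid=grid, T=T.copy(), T_min=T.copy())
        T_ref, Tmin_ref = T.copy(), T.copy()
        dt = 0.4 * stable_dt_bound(T, props, grid)
        for _ in range(10):
            state = step_temperature(state, D, Q, props, dt, check_stability=False)
            T_ref, Tmin_ref = brute_force_step(
                T_ref, Tmin_ref, D, Q, props, dt, grid.spacing_mm
            )
        assert np.array_equal(state.T, T_ref)
        assert np.array_equal(state.T_min, Tmin_ref)

    def test_maximum_principle_under_freezing(self, props):
        """With only a cold Dirichlet probe, temperatures stay within
        [probe temperature, body temperature] at every step."""
        grid = VoxelGrid((16, 16, 16), (2.0, 2.0, 2.0))
        state = ThermalState.initial(grid, props.T_body)
        D = grid.zeros()
        mask = grid.zeros(dtype=bool)
        mask[7:9, 7:9, 7:9] = True
        dt = 0.8 * conservative_dt_bound(props, grid)
        for _ in range(300):
            state = step_temperature(
                state, D, None, props, dt,
                dirichlet_mask=mask, dirichlet_values=-140.0,
                check_stability=False,
            )
            assert state.T.min() >= -140.0 - 1e-9
            assert state.T.max() <= props.T_body + 1e-9

    def test_t_min_is_running_minimum(self, props):
        grid = VoxelGrid((10, 10, 10), (2.0, 2.0, 2.0))
        state = ThermalState.initial(grid, props.T_body)
        mask = grid.zeros(dtype=bool)
        mask[4:6, 4:6, 4:6] = True
        D = grid.zeros()
        dt = 0.8 * stable_dt_bound(state.T, props, grid)
        prev_tmin = state.T_min
        # freeze then actively thaw; T rises but T_min must not
        for probe_T in (-100.0, -100.0, 20.0, 20.0):
            for _ in range(50):
                state = step_temperature(
                    state, D, None, props, dt,
                    dirichlet_mask=mask, dirichlet_values=probe_T,
                    check_stability=False,
                )
                assert np.all(state.T_min <= prev_tmin + 1e-12)
                assert np.all(state.T_min <= state.T + 1e-12)
                prev_tmin = state.T_min


class TestGridConvergence:
    def test_iceball_volume_stable_under_refinement(self, props):
        """Halving the spacing from 2 mm to 1 mm changes the ice-ball
        volume of a fixed freezing scenario by < 5%.

        A 6 mm spherical cold probe is rasterized on each grid (the
        Dirichlet surface then sits at voxel centres on both, so the
        probe geometry is resolution-consistent) and the thermal
        solution's 0 degC isotherm volume is compared.
        """
        scenarios = []
        for spacing, n in ((2.0, 32), (1.0, 64)):
            grid = VoxelGrid((n, n, n), (spacing,) * 3)
            X, Y, Z = grid.coordinate_fields()
            c = 0.5 * spacing * (n - 1)
            probe = (X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2 <= 6.0**2
            scenarios.append((grid, probe))
        volumes = {}
        for grid, probe in scenarios:
            state = ThermalState.initial(grid, props.T_body)
            D = grid.zeros()
            dt_cap = 0.8 * conservative_dt_bound(props, grid)
            n_steps = int(np.ceil(240.0 / dt_cap))
            dt = 240.0 / n_steps
            for _ in range(n_steps):
                state = step_temperature(
                    state, D, None, props, dt,
                    dirichlet_mask=probe, dirichlet_values=-140.0,
                    check_stability=False,
                )
            volumes[grid.spacing_mm[0]] = (
                float((state.T_min <= 0.0).sum()) * grid.voxel_volume_cm3
            )
        assert volumes[1.0] == pytest.approx(volumes[2.0], rel=0.05)
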