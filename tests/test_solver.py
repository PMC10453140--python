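"""Finite-volume solver: grid geometry, heat/mass steps, coupling, full runs."""

import math

import numpy as np
import pytest

from rfdry import experiment
from rfdry.emfield import RFConfig
from rfdry.properties import MaterialProperties
from rfdry.solver import (
    BoundarySpec,
    FaceBC,
    Grid,
    PicardError,
    SimState,
    SolverConfig,
    StageTransport,
    assemble_heat_step,
    assemble_mass_step,
    run,
    step_coupled,
)

from conftest import insulated_side_bounds, uniform_state


class TestGrid:
    def test_cell_volumes_sum_to_cylinder(self):
        g = Grid(radius=0.015, thickness=0.008, nr=7, nz=5)
        assert np.sum(g.vol) == pytest.approx(
            math.pi * 0.015**2 * 0.008, rel=1e-12
        )

    def test_minimum_resolution_enforced(self):
        with pytest.raises(ValueError):
            Grid(nr=3, nz=8)
        with pytest.raises(ValueError):
            Grid(nr=8, nz=2)


class TestHeatStep:
    def test_insulated_no_source_is_steady(self, constant_props):
        g = Grid(nr=4, nz=4)
        st = uniform_state(g, 40.0, 500.0)
        bounds = BoundarySpec(h_T=0.0, h_m=0.0, top=FaceBC(False, False),
                              side=FaceBC(False, False))
        T, _, _ = assemble_heat_step(st, g, constant_props, bounds, 0.0, 1.0)
        assert np.allclose(T, 40.0, atol=1e-12)

    def test_uniform_source_lumped_energy_balance(self, constant_props):
        # insulated, constant props: dT per step = Q·dt/(ρs·Cp) exactly
        g = Grid(nr=4, nz=4)
        st = uniform_state(g, 30.0, 500.0)
        bounds = BoundarySpec(h_T=0.0, h_m=0.0, top=FaceBC(False, False),
                              side=FaceBC(False, False))
        Q, dt = 2.0e5, 1.0
        T, _, _ = assemble_heat_step(st, g, constant_props, bounds, Q, dt)
        expected = 30.0 + Q * dt / (constant_props.rho_s * 2.0e3)
        assert np.allclose(T, expected, rtol=1e-12)

    def test_zero_conductivity_raises(self):
        props = MaterialProperties(k_coeffs=(0.0, 0.0, 0.0), k_floor=0.0)
        g = Grid(nr=4, nz=4)
        st = uniform_state(g, 30.0, 500.0)
        with pytest.raises(ValueError, match="singular"):
            assemble_heat_step(st, g, props, BoundarySpec(), 0.0, 1.0)

    def test_maximum_principle_pure_conduction(self, constant_props):
        # convective heating, no evaporation: T stays within [T0, T_air]
        g = Grid(nr=4, nz=12)
        st = uniform_state(g, 22.0, 500.0)
        bounds = insulated_side_bounds(h_T=35.7, h_m=0.0, T_air=60.0)
        state = st
        for _ in range(200):
            T, _, _ = assemble_heat_step(state, g, constant_props, bounds, 0.0, 5.0)
            assert T.min() >= 22.0 - 1e-9 and T.max() <= 60.0 + 1e-9
            state = SimState(state.t + 5.0, T, state.C, state.rho_dm)
        assert state.T.max() > 40.0  # and it does actually heat


class TestMassStep:
    def test_closed_boundaries_conserve_total_moisture(self):
        g = Grid(nr=5, nz=6)
        C = 400.0 + 200.0 * np.random.default_rng(1).random((g.nz, g.nr))
        st = SimState(0.0, np.full((g.nz, g.nr), 30.0), C, 224.4)
        bounds = BoundarySpec(h_m=0.0, top=FaceBC(True, False),
                              side=FaceBC(False, False))
        total0 = np.sum(st.C * g.vol)
        Cn, jt, js = assemble_mass_step(st, g, 5e-9, 0.0, bounds, 10.0)
        assert np.sum(Cn * g.vol) == pytest.approx(total0, rel=1e-10)
        assert np.all(jt == 0.0)

    def test_equilibrium_state_is_fixed_point(self):
        g = Grid(nr=4, nz=4)
        bounds = insulated_side_bounds(C_eq=11.22, h_m=1e-6)
        st = uniform_state(g, 30.0, 11.22)
        Cn, _, _ = assemble_mass_step(st, g, 5e-9, 1e-6, bounds, 60.0)
        assert np.allclose(Cn, 11.22, rtol=1e-12)

    def test_implicit_outflux_matches_content_change(self):
        g = Grid(nr=4, nz=8)
        bounds = insulated_side_bounds(C_eq=0.0, h_m=2e-6)
        st = uniform_state(g, 30.0, 800.0)
        dt = 30.0
        Cn, jt, _ = assemble_mass_step(st, g, 5e-9, 2e-6, bounds, dt)
        removed = np.sum((st.C - Cn) * g.vol)
        outflux = np.sum(jt * g.ring_area) * dt
        assert removed == pytest.approx(outflux, rel=1e-10)

    def test_negative_diffusivity_rejected(self):
        g = Grid(nr=4, nz=4)
        st = uniform_state(g, 30.0, 500.0)
        with pytest.raises(ValueError):
            assemble_mass_step(st, g, -1e-9, 1e-6, BoundarySpec(), 1.0)


class TestCoupledStep:
    def test_equilibrium_is_exact_fixed_point_single_iteration(self, default_props):
        g = Grid(nr=4, nz=4)
        bounds = BoundarySpec(T_air=60.0, C_eq=11.22)
        st = uniform_state(g, 60.0, 11.22)
        cfg = SolverConfig()
        new, fluxes, stored, n_pic = step_coupled(
            st, g, default_props, bounds, cfg, cfg.transport_ha
        )
        assert n_pic == 1
        assert np.allclose(new.T, 60.0, atol=1e-9)
        assert np.allclose(new.C, 11.22, rtol=1e-9)

    def test_rf_strictly_raises_center_temperature(self, default_props):
        g = Grid(nr=6, nz=6)
        bounds = BoundarySpec()
        cfg = SolverConfig()
        st = uniform_state(g, 40.0, 800.0)
        off, _, _, _ = step_coupled(st.copy(), g, default_props, bounds, cfg,
                                    cfg.transport_ha)
        st_on = st.copy()
        st_on.rf_on = True
        from rfdry.solver import _FieldCoupler
        coupler = _FieldCoupler(RFConfig(), default_props, g, cfg)
        on, _, _, _ = step_coupled(st_on, g, default_props, bounds, cfg,
                                   cfg.transport_rf, coupler)
        ci = g.center_index
        assert on.T[ci] > off.T[ci]

    def test_picard_nonconvergence_reports_smaller_dt(self, default_props):
        g = Grid(nr=4, nz=4)
        cfg = SolverConfig(dt=500.0, max_picard=1, tol_T=1e-12)
        st = uniform_state(g, 22.0, 800.0)
        with pytest.raises(PicardError, match="dt"):
            step_coupled(st, g, default_props, BoundarySpec(), cfg,
                         cfg.transport_ha)


class TestRun:
    def test_schedule_gaps_rejected(self):
        stages = [experiment.Stage(0.0, 100.0, False),
                  experiment.Stage(150.0, 300.0, False)]
        with pytest.raises(ValueError, match="tile"):
            run(stages, grid=Grid(nr=4, nz=4))

    def test_hot_air_moisture_monotone_nonincreasing(self):
        res = _short_ha()
        assert np.all(np.diff(res.M_db) <= 1e-12)

    def test_record_cadence_and_initial_conditions(self):
        res = _short_ha()
        assert res.t[0] == 0.0
        assert res.T_center[0] == pytest.approx(22.0)
        assert res.M_db[0] == pytest.approx(0.796 / (1.0 - 0.796), rel=1e-9)
        assert np.all(np.diff(res.t) == pytest.approx(60.0))

    def test_audits_close_on_short_run(self):
        res = _short_ha()
        assert res.mass_balance_error() < 1e-10
        assert res.energy_balance_error() < 1e-10

    def test_time_to_moisture_interpolates(self):
        res = _short_ha()
        mid = 0.5 * (res.M_db[0] + res.M_db[-1])
        t_hit = res.time_to_moisture(mid)
        assert res.t[0] < t_hit < res.t[-1]
        assert res.time_to_moisture(-1.0) == math.inf


def _short_ha():
    sched = experiment.make_schedule("HA", t_end=600.0)
    cfg = SolverConfig(dt=5.0, record_every=60.0)
    return run(sched, grid=Grid(nr=4, nz=6), cfg=cfg)


class TestFieldModes:
    def test_layered_and_2d_modes_heat_similarly(self):
        # fringing changes the deposited power only modestly for a thin slice
        sched = experiment.make_schedule("E-HA+RF", t_end=1800.0)
        g = Grid(nr=6, nz=6)
        r_lay = run(sched, grid=g, cfg=SolverConfig(dt=30.0, field_mode="layered"))
        r_2d = run(sched, grid=g, cfg=SolverConfig(dt=30.0, field_mode="2d"))
        rise_lay = r_lay.T_center[-1] - 22.0
        rise_2d = r_2d.T_center[-1] - 22.0
        assert rise_2d == pytest.approx(rise_lay, rel=0.5)
        assert r_2d.audit["field_solves"] > 0

    def test_field_cache_reuses_solution_between_refreshes(self):
        sched = experiment.make_schedule("E-HA+RF", t_end=1800.0)
        res = run(sched, grid=Grid(nr=4, nz=4), cfg=SolverConfig(dt=10.0))
        assert 0 < res.audit["field_solves"] < 180  # far fewer solves than steps


class TestSelfConvergence:
    """Discretisation-error checks over the full 4.5 h horizon."""

    def test_halving_dt_barely_changes_center_trajectory(self):
        r1 = experiment.simulate_scenario("HA", cfg=SolverConfig(dt=1.0))
        r2 = experiment.simulate_scenario("HA", cfg=SolverConfig(dt=0.5))
        assert np.max(np.abs(r1.T_center - r2.T_center)) < 0.2

    def test_doubling_grid_barely_changes_final_center_temperature(self):
        r1 = experiment.simulate_scenario("E-HA+RF", grid=Grid(nr=10, nz=8))
        r2 = experiment.simulate_scenario("E-HA+RF", grid=Grid(nr=20, nz=16))
        assert abs(r1.T_center[-1] - r2.T_center[-1]) < 0.3
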