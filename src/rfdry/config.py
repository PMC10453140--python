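"""Schema-validated run configuration and time-series file I/O.

Configurations are YAML documents with nested blocks ``material``, ``air``,
``rf``, ``geometry``, ``boundary``, ``solver``, ``schedule``, ``output`` and a
global ``seed``.  Every key has a documented default, so the empty document is
a complete configuration (the canonical hot-air run).  Unknown keys are
rejected with the offending path.  Units: SI metres/seconds throughout,
temperatures in °C.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import experiment, kinetics, properties, solver
from .emfield import Layer, RFConfig

__all__ = ["RunConfig", "load_config", "write_timeseries", "read_timeseries",
           "TIMESERIES_COLUMNS"]

TIMESERIES_COLUMNS = [
    "t_s", "T_center_C", "T_surface_mean_C", "M_db", "M_wb", "M_db_center",
    "rf_on", "Q_rf_total_W",
]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MaterialBlock(_Block):
    cp_coeffs: tuple[float, float, float] = properties.CP_COEFFS
    k_coeffs: tuple[float, float, float] = properties.K_COEFFS
    eps_prime_coeffs: tuple[float, float, float] = properties.EPS_PRIME_COEFFS
    eps_loss_coeffs: tuple[float, float, float, float] = properties.EPS_LOSS_COEFFS
    rho_s: float = Field(1100.0, gt=0, description="bulk density, kg/m³")
    sigma: float = Field(0.0, ge=0, description="ionic conductivity, S/m")
    Me: float = Field(0.05, ge=0, description="equilibrium moisture, kg/kg db")
    cp_floor: float = 0.85
    k_floor: float = 0.05


class AirBlock(_Block):
    T_air: float = Field(60.0, description="drying-air temperature, °C")
    velocity: float = Field(2.5, ge=0, description="air speed, m/s")
    char_length: float = Field(0.03, gt=0, description="flat-plate length for Re, m")


class LayerBlock(_Block):
    thickness: float = Field(gt=0)
    eps_real: float = 1.0
    eps_imag: float = 0.0
    sigma: float = 0.0


class RFBlock(_Block):
    f: float = Field(27.12e6, gt=0, description="RF frequency, Hz")
    gap: float = Field(0.110, gt=0, description="electrode spacing, m")
    v_top: float = Field(15e3, gt=0, description="top-electrode potential, V")
    air_below: float = Field(0.020, ge=0, description="tray offset below slice, m")
    plate_area: float = Field(0.80 * 0.43, gt=0)
    field_mode: str = Field("layered", pattern="^(layered|2d)$")
    layers: list[LayerBlock] | None = None

    @model_validator(mode="after")
    def _layers_fill_gap(self):
        if self.layers is not None:
            total = sum(la.thickness for la in self.layers)
            if abs(total - self.gap) > 1e-9 * max(self.gap, 1.0):
                raise ValueError(
                    f"rf.layers thicknesses sum to {total:g} but rf.gap is {self.gap:g}"
                )
        return self


class GeometryBlock(_Block):
    radius: float = Field(0.015, gt=0, description="slice radius, m")
    thickness: float = Field(0.008, gt=0, description="slice thickness, m")
    nr: int = Field(10, ge=4)
    nz: int = Field(8, ge=4)


class BoundaryBlock(_Block):
    h_T: float | None = Field(
        None, description="W/m²/K; null → laminar flat-plate correlation"
    )
    h_m_ha: float = Field(1.56e-6, ge=0, description="HA-stage h_m, m/s")
    h_m_rf: float = Field(2.5e-6, ge=0, description="RF-stage h_m, m/s")
    D_eff_ha: float = Field(6.25e-9, gt=0, description="HA-stage D_eff, m²/s")
    D_eff_rf: float = Field(1.0e-8, gt=0, description="RF-stage D_eff, m²/s")
    side_convective: bool = True
    side_evaporative: bool = False
    bottom_adiabatic: bool = True


class SolverBlock(_Block):
    dt: float = Field(1.0, gt=0, description="time step, s")
    max_picard: int = Field(8, ge=1)
    tol_T: float = Field(1e-3, gt=0, description="Picard tolerance on T, °C")
    tol_C: float = Field(1e-6, gt=0, description="Picard tolerance on C, relative")
    field_update_dT: float = Field(0.5, gt=0)
    field_update_dM: float = Field(0.05, gt=0)
    record_every: float = Field(60.0, gt=0, description="output cadence, s")
    T_init: float = Field(22.0, description="initial (room) temperature, °C")
    w_wb_init: float = Field(0.796, gt=0, lt=1, description="initial wet-basis moisture")


class StageBlock(_Block):
    start: float = Field(ge=0)
    end: float = Field(gt=0)
    rf_on: bool = False


class ScheduleBlock(_Block):
    scenario: str | None = Field("HA", description="canonical name or null for custom")
    t_end: float = Field(16200.0, gt=0, description="total drying time, s")
    stages: list[StageBlock] | None = None

    @model_validator(mode="after")
    def _one_of(self):
        if self.scenario is None and not self.stages:
            raise ValueError("schedule needs either a scenario name or explicit stages")
        if self.scenario is not None and self.scenario not in experiment.SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; valid: {list(experiment.SCENARIOS)}"
            )
        return self


class OutputBlock(_Block):
    timeseries: str | None = None
    snapshots_dir: str | None = None


class RunConfig(_Block):
    material: MaterialBlock = Field(default_factory=MaterialBlock)
    air: AirBlock = Field(default_factory=AirBlock)
    rf: RFBlock = Field(default_factory=RFBlock)
    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    boundary: BoundaryBlock = Field(default_factory=BoundaryBlock)
    solver: SolverBlock = Field(default_factory=SolverBlock)
    schedule: ScheduleBlock = Field(default_factory=ScheduleBlock)
    output: OutputBlock = Field(default_factory=OutputBlock)
    seed: int = 0

    # -- builders for the runtime objects -------------------------------
    def build_props(self) -> properties.MaterialProperties:
        m = self.material
        return properties.MaterialProperties(
            cp_coeffs=m.cp_coeffs, k_coeffs=m.k_coeffs,
            eps_prime_coeffs=m.eps_prime_coeffs, eps_loss_coeffs=m.eps_loss_coeffs,
            rho_s=m.rho_s, sigma=m.sigma, Me=m.Me,
            cp_floor=m.cp_floor, k_floor=m.k_floor,
        )

    def build_grid(self) -> solver.Grid:
        g = self.geometry
        return solver.Grid(radius=g.radius, thickness=g.thickness, nr=g.nr, nz=g.nz)

    def build_air(self) -> properties.AirProperties:
        return properties.air_properties(self.air.T_air)

    def derived_h_T(self) -> float:
        if self.boundary.h_T is not None:
            return self.boundary.h_T
        return kinetics.heat_transfer_coeff(
            self.air.velocity, self.air.char_length, self.build_air()
        )

    def build_bounds(self) -> solver.BoundarySpec:
        b = self.boundary
        rho_dm = self.material.rho_s * (1.0 - self.solver.w_wb_init)
        return solver.BoundarySpec(
            h_T=self.derived_h_T(),
            h_m=b.h_m_ha,
            T_air=self.air.T_air,
            C_eq=rho_dm * self.material.Me,
            side=solver.FaceBC(b.side_convective, b.side_evaporative),
            bottom=solver.FaceBC(not b.bottom_adiabatic, not b.bottom_adiabatic),
        )

    def build_solver_cfg(self) -> solver.SolverConfig:
        s, b = self.solver, self.boundary
        return solver.SolverConfig(
            dt=s.dt, max_picard=s.max_picard, tol_T=s.tol_T, tol_C=s.tol_C,
            field_mode=self.rf.field_mode,
            field_update_dT=s.field_update_dT, field_update_dM=s.field_update_dM,
            record_every=s.record_every,
            transport_ha=solver.StageTransport(b.D_eff_ha, b.h_m_ha),
            transport_rf=solver.StageTransport(b.D_eff_rf, b.h_m_rf),
        )

    def build_rf(self) -> RFConfig:
        r = self.rf
        layers = None
        if r.layers is not None:
            layers = [
                Layer(la.thickness, la.eps_real - 1j * la.eps_imag, la.sigma)
                for la in r.layers
            ]
        return RFConfig(
            f=r.f, gap=r.gap, V_top=r.v_top, plate_area=r.plate_area,
            air_below=r.air_below,
            sample_thickness=self.geometry.thickness, layers=layers,
        )

    def build_schedule(self) -> experiment.DryingSchedule:
        sc = self.schedule
        if sc.stages:
            stages = [experiment.Stage(s.start, s.end, s.rf_on) for s in sc.stages]
            return experiment.DryingSchedule(name="custom", stages=stages)
        return experiment.make_schedule(sc.scenario, t_end=sc.t_end)

    def run(self, scenario: str | None = None) -> solver.SimulationResult:
        """Execute the configured simulation (scenario overrides the config)."""
        schedule = (
            experiment.make_schedule(scenario, t_end=self.schedule.t_end)
            if scenario is not None
            else self.build_schedule()
        )
        return solver.run(
            schedule,
            grid=self.build_grid(),
            props=self.build_props(),
            bounds=self.build_bounds(),
            cfg=self.build_solver_cfg(),
            rf=self.build_rf(),
            T_init=self.solver.T_init,
            w_wb_init=self.solver.w_wb_init,
        )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML configuration; None or empty → all defaults."""
    if path is None:
        return RunConfig()
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"configuration file not found: {p}")
    data = yaml.safe_load(p.read_text())
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ValueError(f"{p}: top level must be a mapping")
    return RunConfig.model_validate(data)


def dump_config(cfg: RunConfig) -> str:
    """Serialise a configuration back to YAML (load∘dump idempotent)."""
    return yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False)


def write_timeseries(result: solver.SimulationResult, path: str | Path) -> None:
    """Write the recorded series as CSV with the fixed documented header."""
    df = result.to_dataframe()
    df.to_csv(path, index=False, float_format="%.10g")


def read_timeseries(path: str | Path) -> pd.DataFrame:
    """Read a time-series CSV written by :func:`write_timeseries`."""
    p = Path(path)
    try:
        df = pd.read_csv(p)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {p}: {exc}") from exc
    missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{p}: missing columns {missing}")
    return df


def write_field_snapshot(sol, path: str | Path) -> None:
    """Dump |E| and Q_rf as a delimited grid file with r/z headers (metres)."""
    with open(path, "w") as fh:
        fh.write("# r_m: " + " ".join(f"{v:.6g}" for v in sol.r) + "\n")
        fh.write("# z_m: " + " ".join(f"{v:.6g}" for v in sol.z) + "\n")
        fh.write("# block 1: |E| (V/m) rows=z cols=r; block 2: Q_rf (W/m³)\n")
        np.savetxt(fh, sol.E_mag, fmt="%.8g")
        fh.write("\n")
        np.savetxt(fh, sol.Q_rf, fmt="%.8g")
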