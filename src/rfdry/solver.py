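"""Coupled heat and moisture transport in an axisymmetric slice.

The slice is a cylinder (radius R, thickness H) resting on an impermeable
tray.  Interior transport is conduction plus the RF source for heat and
Fickian diffusion for moisture::

    ρs·Cp·∂T/∂t = ∇·(k∇T) + Q_rf
    ∂C/∂t       = ∇·(D_eff∇C)

with C the liquid-water concentration (kg/m³).  Boundary faces combine
convective heat gain with an evaporative sink tied to the moisture outflux::

    k∇T·n = h_T·(T_air − T_s) − h_fg·h_m·(C_s − C_eq)
    −D_eff∇C·n = h_m·(C_s − C_eq)

Discretisation is cell-centred finite volumes (conservative by construction,
so the mass and energy audits close to solver precision) with backward-Euler
time stepping and Picard lagging of the temperature/moisture-dependent
properties — unconditionally stable at the 1 s default step.  Boundary
exchange uses the series conductance ``U = 1/(1/h + δ/(2·k_cell))`` chaining
the film coefficient with the half-cell conduction path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import emfield
from .properties import MaterialProperties, latent_heat, wet_basis_fraction

__all__ = [
    "Grid",
    "FaceBC",
    "BoundarySpec",
    "StageTransport",
    "SolverConfig",
    "SimState",
    "SimulationResult",
    "assemble_heat_step",
    "assemble_mass_step",
    "step_coupled",
    "run",
]

logger = logging.getLogger(__name__)


class PicardError(RuntimeError):
    """Nonlinear iteration failed to converge; try a smaller time step."""


@dataclass
class Grid:
    """Axisymmetric finite-volume grid for the slice interior.

    Cells are indexed ``[iz, ir]`` with iz=0 at the tray and iz=nz−1 at the
    exposed top surface.
    """

    radius: float = 0.015
    thickness: float = 0.008
    nr: int = 10
    nz: int = 8

    def __post_init__(self) -> None:
        if self.nr < 4 or self.nz < 4:
            raise ValueError("need nr, nz >= 4")
        if self.radius <= 0 or self.thickness <= 0:
            raise ValueError("radius and thickness must be positive")
        self.r_edges = np.linspace(0.0, self.radius, self.nr + 1)
        self.z_edges = np.linspace(0.0, self.thickness, self.nz + 1)
        self.rc = 0.5 * (self.r_edges[:-1] + self.r_edges[1:])
        self.zc = 0.5 * (self.z_edges[:-1] + self.z_edges[1:])
        self.dr = self.radius / self.nr
        self.dz = self.thickness / self.nz
        # exact axisymmetric weights: ring areas (horizontal faces) and volumes
        self.ring_area = math.pi * (self.r_edges[1:] ** 2 - self.r_edges[:-1] ** 2)
        self.side_area_outer = 2.0 * math.pi * self.radius * self.dz
        self.radial_face_area = 2.0 * math.pi * self.r_edges[1:-1] * self.dz
        self.vol = np.broadcast_to(self.ring_area, (self.nz, self.nr)).copy() * self.dz

    @property
    def total_volume(self) -> float:
        return math.pi * self.radius**2 * self.thickness

    @property
    def center_index(self) -> tuple[int, int]:
        """Cell nearest the slice mid-plane on the axis."""
        return (self.nz // 2, 0)


@dataclass(frozen=True)
class FaceBC:
    convective: bool = False
    evaporative: bool = False


@dataclass
class BoundarySpec:
    """External exchange conditions.

    Defaults: the exposed top face both heats convectively and evaporates;
    the rim exchanges heat only; the tray face is adiabatic and impermeable.
    """

    h_T: float = 35.7  # W/m²/K
    h_m: float = 1.56e-6  # m/s
    T_air: float = 60.0  # °C
    C_eq: float = 11.22  # kg/m³ (= rho_dm·Me)
    h_fg: float | None = None  # J/kg; None → water correlation at T_air
    top: FaceBC = field(default_factory=lambda: FaceBC(True, True))
    side: FaceBC = field(default_factory=lambda: FaceBC(True, False))
    bottom: FaceBC = field(default_factory=lambda: FaceBC(False, False))

    def __post_init__(self) -> None:
        if self.h_T < 0 or self.h_m < 0:
            raise ValueError("transfer coefficients must be nonnegative")
        if self.h_fg is None:
            self.h_fg = float(latent_heat(self.T_air))


@dataclass(frozen=True)
class StageTransport:
    """Moisture-transport constants used while a stage is active.

    The effective diffusivity is held constant within a drying stage; RF
    stages carry their own (larger) D_eff and h_m, reflecting stage-wise
    kinetics fits.
    """

    D_eff: float
    h_m: float

    def __post_init__(self) -> None:
        if self.D_eff < 0:
            raise ValueError("negative D_eff")


@dataclass
class SolverConfig:
    dt: float = 1.0  # s
    max_picard: int = 8
    tol_T: float = 1e-3  # °C, absolute
    tol_C: float = 1e-6  # relative
    field_mode: str = "layered"  # or "2d"
    field_update_dT: float = 0.5  # °C drift triggering a field re-solve
    field_update_dM: float = 0.05  # kg/kg db drift triggering a re-solve
    record_every: float = 60.0  # s
    # stage-wise transport: HA (rf off) and RF (rf on) values
    transport_ha: StageTransport = field(
        default_factory=lambda: StageTransport(D_eff=6.25e-9, h_m=1.56e-6)
    )
    transport_rf: StageTransport = field(
        default_factory=lambda: StageTransport(D_eff=1.0e-8, h_m=2.5e-6)
    )

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tol_T <= 0 or self.tol_C <= 0:
            raise ValueError("tolerances must be positive")
        if self.field_mode not in ("layered", "2d"):
            raise ValueError("field_mode must be 'layered' or '2d'")


@dataclass
class SimState:
    """Temperature and moisture fields at time t."""

    t: float
    T: np.ndarray  # °C, shape (nz, nr)
    C: np.ndarray  # kg/m³, shape (nz, nr)
    rho_dm: float  # dry matter per unit volume, kg/m³
    rf_on: bool = False

    @property
    def M_db(self) -> np.ndarray:
        return self.C / self.rho_dm

    @property
    def W_wb(self) -> np.ndarray:
        return wet_basis_fraction(self.M_db)

    def copy(self) -> "SimState":
        return SimState(self.t, self.T.copy(), self.C.copy(), self.rho_dm, self.rf_on)


def _props_eval(props: MaterialProperties, T, W):
    """Evaluate Cp [J/kg/K] and k clamping inputs to the fitted window."""
    Tc = np.clip(T, *props.T_range)
    Wc = np.clip(W, *props.W_range)
    inner = replace(props, validate_inputs=False)
    return inner.specific_heat_J(Tc, Wc), inner.thermal_conductivity(Tc, Wc)


def _five_point_matrix(grid: Grid, diag_extra, G_r, G_z):
    """Assemble the symmetric diffusion operator plus a diagonal term.

    ``G_r[(iz, ir)]`` couples (iz, ir)↔(iz, ir+1); ``G_z[(iz, ir)]`` couples
    (iz, ir)↔(iz+1, ir); ``diag_extra`` holds the time/boundary terms.
    """
    nz, nr = grid.nz, grid.nr
    n = nz * nr
    diag = diag_extra.ravel().astype(float).copy()
    # accumulate face conductances into the diagonal
    gr = np.zeros((nz, nr))
    gr[:, :-1] += G_r
    gr[:, 1:] += G_r
    gz = np.zeros((nz, nr))
    gz[:-1, :] += G_z
    gz[1:, :] += G_z
    diag += (gr + gz).ravel()

    off_r = np.zeros((nz, nr))
    off_r[:, :-1] = -G_r  # coupling to ir+1
    off_z = np.zeros((nz, nr))
    off_z[:-1, :] = -G_z  # coupling to iz+1
    A = sp.diags(
        [diag, off_r.ravel()[:-1], off_r.ravel()[:-1], off_z.ravel()[:-nr], off_z.ravel()[:-nr]],
        [0, 1, -1, nr, -nr],
        format="csc",
    )
    return A


def _series_U(h: float, half_path: float, k_cell: np.ndarray) -> np.ndarray:
    """Film coefficient in series with the half-cell conduction path."""
    if h == 0:
        return np.zeros_like(k_cell)
    return 1.0 / (1.0 / h + half_path / k_cell)


def assemble_heat_step(
    state: SimState,
    grid: Grid,
    props: MaterialProperties,
    bounds: BoundarySpec,
    q_rf_field: np.ndarray | float,
    dt: float,
    j_evap_top: np.ndarray | None = None,
    j_evap_side: np.ndarray | None = None,
    T_props: np.ndarray | None = None,
    C_new: np.ndarray | None = None,
):
    """One backward-Euler heat step; returns (T_new, cp_field, flux report).

    ``j_evap_*`` are evaporative mass fluxes (kg/m²/s, ≥0 outward) applied as
    latent-heat sinks on the corresponding faces; ``T_props`` is the Picard
    iterate at which Cp and k are evaluated (defaults to the old field).
    """
    nz, nr = grid.nz, grid.nr
    T_old = state.T
    W = state.W_wb if C_new is None else C_new / state.rho_dm / (1.0 + C_new / state.rho_dm)
    cp, k = _props_eval(props, T_old if T_props is None else T_props, W)
    cp = np.broadcast_to(cp, (nz, nr))
    k = np.broadcast_to(np.asarray(k, float), (nz, nr))
    if np.all(k == 0):
        raise ValueError("singular heat operator: thermal conductivity is zero")

    harm = lambda a, b: 2.0 * a * b / (a + b)
    G_r = harm(k[:, :-1], k[:, 1:]) * grid.radial_face_area[None, :] / grid.dr
    G_z = harm(k[:-1, :], k[1:, :]) * grid.ring_area[None, :] / grid.dz

    cap = props.rho_s * cp * grid.vol / dt
    diag_extra = cap.copy()
    rhs = cap * T_old + np.broadcast_to(np.asarray(q_rf_field, float), (nz, nr)) * grid.vol

    U_top = np.zeros(nr)
    if bounds.top.convective and bounds.h_T > 0:
        U_top = _series_U(bounds.h_T, grid.dz / 2.0, k[-1, :])
        diag_extra[-1, :] += U_top * grid.ring_area
        rhs[-1, :] += U_top * grid.ring_area * bounds.T_air
    U_side = np.zeros(nz)
    if bounds.side.convective and bounds.h_T > 0:
        U_side = _series_U(bounds.h_T, grid.dr / 2.0, k[:, -1])
        diag_extra[:, -1] += U_side * grid.side_area_outer
        rhs[:, -1] += U_side * grid.side_area_outer * bounds.T_air
    if j_evap_top is not None:
        rhs[-1, :] -= bounds.h_fg * j_evap_top * grid.ring_area
    if j_evap_side is not None:
        rhs[:, -1] -= bounds.h_fg * j_evap_side * grid.side_area_outer

    A = _five_point_matrix(grid, diag_extra, G_r, G_z)
    T_new = spla.spsolve(A, rhs.ravel()).reshape(nz, nr)

    conv_in = float(np.sum(U_top * grid.ring_area * (bounds.T_air - T_new[-1, :])))
    conv_in += float(np.sum(U_side * grid.side_area_outer * (bounds.T_air - T_new[:, -1])))
    evap_out = 0.0
    if j_evap_top is not None:
        evap_out += float(bounds.h_fg * np.sum(j_evap_top * grid.ring_area))
    if j_evap_side is not None:
        evap_out += float(bounds.h_fg * np.sum(j_evap_side * grid.side_area_outer))
    rf_in = float(np.sum(np.broadcast_to(np.asarray(q_rf_field, float), (nz, nr)) * grid.vol))
    fluxes = {"conv_in_W": conv_in, "evap_out_W": evap_out, "rf_in_W": rf_in,
              "U_top": U_top, "U_side": U_side}
    return T_new, cp, fluxes


def assemble_mass_step(
    state: SimState,
    grid: Grid,
    D_eff: float,
    h_m: float,
    bounds: BoundarySpec,
    dt: float,
):
    """One backward-Euler moisture step; returns (C_new, j_top, j_side).

    Evaporative faces remove water at ``U_m·(C_s − C_eq)``; all other faces
    are impermeable.  The scheme is conservative: the cell-volume-integrated
    change equals the boundary outflux exactly.
    """
    if D_eff < 0:
        raise ValueError("negative D_eff")
    nz, nr = grid.nz, grid.nr
    C_old = state.C
    D = np.full((nz, nr), float(D_eff))

    G_r = D[:, :-1] * grid.radial_face_area[None, :] / grid.dr  # uniform D: plain mean
    G_z = D[:-1, :] * grid.ring_area[None, :] / grid.dz

    cap = grid.vol / dt
    diag_extra = cap.copy()
    rhs = cap * C_old

    Um_top = np.zeros(nr)
    if bounds.top.evaporative and h_m > 0 and D_eff > 0:
        Um_top = _series_U(h_m, grid.dz / 2.0, D[-1, :])
        diag_extra[-1, :] += Um_top * grid.ring_area
        rhs[-1, :] += Um_top * grid.ring_area * bounds.C_eq
    Um_side = np.zeros(nz)
    if bounds.side.evaporative and h_m > 0 and D_eff > 0:
        Um_side = _series_U(h_m, grid.dr / 2.0, D[:, -1])
        diag_extra[:, -1] += Um_side * grid.side_area_outer
        rhs[:, -1] += Um_side * grid.side_area_outer * bounds.C_eq

    A = _five_point_matrix(grid, diag_extra, G_r, G_z)
    C_new = spla.spsolve(A, rhs.ravel()).reshape(nz, nr)
    j_top = Um_top * (C_new[-1, :] - bounds.C_eq)
    j_side = Um_side * (C_new[:, -1] - bounds.C_eq)
    return C_new, j_top, j_side


def solve_field_2d(
    state: SimState,
    grid: Grid,
    props: MaterialProperties,
    rf: emfield.RFConfig,
) -> emfield.FieldSolution:
    """2-D axisymmetric field solve for the full electrode gap.

    The slice occupies the inner radii between the tray offset and the top
    of the sample; air fills the rest (radially out to 3R).  Permittivity is
    evaluated per sample cell from the current (T, W) fields, clipped to the
    regression validity window.
    """
    inner = replace(props, validate_inputs=False)
    T = np.clip(state.T, *props.T_range)
    W = np.clip(state.W_wb, *props.W_range)
    r_air = np.linspace(grid.radius, 3.0 * grid.radius, 2 * grid.nr + 1)[1:]
    r_edges = np.concatenate([grid.r_edges, r_air])
    nz_below, nz_above = 4, 8
    z_below = np.linspace(0.0, rf.air_below, nz_below + 1)
    z_sample = rf.air_below + grid.z_edges[1:]
    z_above = np.linspace(rf.air_below + grid.thickness, rf.gap, nz_above + 1)[1:]
    z_edges = np.concatenate([z_below, z_sample, z_above])
    eps = np.ones((z_edges.size - 1, r_edges.size - 1), complex)
    sig = np.zeros((z_edges.size - 1, r_edges.size - 1))
    sl_z = slice(nz_below, nz_below + grid.nz)
    eps[sl_z, : grid.nr] = inner.complex_permittivity(T, W)
    sig[sl_z, : grid.nr] = props.sigma
    sol = emfield.laplace_2d(r_edges, z_edges, eps, sig, rf.f, rf.V_top)
    sol.sample_slices = (sl_z, slice(0, grid.nr))  # type: ignore[attr-defined]
    return sol


class _FieldCoupler:
    """Caches the RF field solution and refreshes it when the state drifts."""

    def __init__(self, rf: emfield.RFConfig, props: MaterialProperties,
                 grid: Grid, cfg: SolverConfig):
        self.rf = rf
        self.props = props
        self.grid = grid
        self.cfg = cfg
        self._T_at_solve = None
        self._M_at_solve = None
        self._Q = np.zeros((grid.nz, grid.nr))
        self.n_solves = 0

    def _needs_update(self, state: SimState) -> bool:
        if self._T_at_solve is None:
            return True
        return (
            float(np.max(np.abs(state.T - self._T_at_solve))) > self.cfg.field_update_dT
            or float(np.max(np.abs(state.M_db - self._M_at_solve))) > self.cfg.field_update_dM
        )

    def q_field(self, state: SimState) -> np.ndarray:
        if not state.rf_on:
            return np.zeros((self.grid.nz, self.grid.nr))
        if self._needs_update(state):
            self._solve(state)
            self._T_at_solve = state.T.copy()
            self._M_at_solve = state.M_db.copy()
        return self._Q

    def _solve(self, state: SimState) -> None:
        self.n_solves += 1
        inner = replace(self.props, validate_inputs=False)
        T = np.clip(state.T, *self.props.T_range)
        W = np.clip(state.W_wb, *self.props.W_range)
        if self.cfg.field_mode == "layered":
            T_m, W_m = float(np.mean(T)), float(np.mean(W))
            eps = complex(inner.complex_permittivity(T_m, W_m))
            stack = self.rf.stack_for_sample(eps, self.props.sigma)
            E = emfield.layered_field(self.rf.V_top, stack, self.rf.f)
            E_s = abs(E[1])
            self._Q = np.full(
                (self.grid.nz, self.grid.nr),
                float(emfield.q_rf(E_s, inner.loss_factor(T_m, W_m), self.rf.f))
                + self.props.sigma * E_s**2,
            )
        else:
            sol = solve_field_2d(state, self.grid, inner, self.rf)
            sl_z, sl_r = sol.sample_slices
            self._Q = np.asarray(sol.Q_rf[sl_z, sl_r], float)


def step_coupled(
    state: SimState,
    grid: Grid,
    props: MaterialProperties,
    bounds: BoundarySpec,
    cfg: SolverConfig,
    transport: StageTransport,
    coupler: _FieldCoupler | None = None,
):
    """Advance one time step: moisture solve, field refresh, Picard heat loop.

    Returns ``(new_state, fluxes, stored_J, n_picard)`` where ``stored_J`` is
    the enthalpy increment consistent with the Cp used in the accepted solve.
    """
    dt = cfg.dt
    q = coupler.q_field(state) if coupler is not None else 0.0
    C_new, j_top, j_side = assemble_mass_step(
        state, grid, transport.D_eff, transport.h_m, bounds, dt
    )
    jt = j_top if bounds.top.evaporative else None
    js = j_side if bounds.side.evaporative else None

    T_it = state.T
    for it in range(cfg.max_picard):
        T_new, cp, fluxes = assemble_heat_step(
            state, grid, props, bounds, q, dt,
            j_evap_top=jt, j_evap_side=js, T_props=T_it, C_new=C_new,
        )
        dT = float(np.max(np.abs(T_new - T_it)))
        T_it = T_new
        if dT < cfg.tol_T:
            break
    else:
        raise PicardError(
            f"Picard stalled at |ΔT|={dT:g} after {cfg.max_picard} iterations; "
            "reduce dt"
        )
    stored = float(np.sum(props.rho_s * cp * grid.vol * (T_new - state.T)))
    new = SimState(state.t + dt, T_new, C_new, state.rho_dm, state.rf_on)
    return new, fluxes, stored, it + 1


@dataclass
class SimulationResult:
    """Recorded time series plus conservation bookkeeping for one run."""

    t: np.ndarray
    T_center: np.ndarray
    T_surface_mean: np.ndarray
    M_db: np.ndarray
    M_wb: np.ndarray
    M_db_center: np.ndarray
    rf_on: np.ndarray
    Q_rf_total_W: np.ndarray
    final_state: SimState
    audit: dict

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_s": self.t,
                "T_center_C": self.T_center,
                "T_surface_mean_C": self.T_surface_mean,
                "M_db": self.M_db,
                "M_wb": self.M_wb,
                "M_db_center": self.M_db_center,
                "rf_on": self.rf_on.astype(int),
                "Q_rf_total_W": self.Q_rf_total_W,
            }
        )

    def mass_balance_error(self) -> float:
        """|Δ(stored water) + evaporated| / initial water, relative."""
        a = self.audit
        removed = a["water_initial_kg"] - a["water_final_kg"]
        return abs(removed - a["evaporated_kg"]) / a["water_initial_kg"]

    def energy_balance_error(self) -> float:
        """|stored − (convective − evaporative + RF)| / total input."""
        a = self.audit
        supplied = abs(a["conv_in_J"]) + abs(a["rf_in_J"]) + abs(a["evap_out_J"])
        if supplied == 0:
            return 0.0
        resid = a["stored_J"] - (a["conv_in_J"] - a["evap_out_J"] + a["rf_in_J"])
        return abs(resid) / supplied

    def time_to_moisture(self, target_M_db: float) -> float:
        """First time the volume-mean M_db reaches the target (linear
        interpolation between records); inf if never reached."""
        below = np.nonzero(self.M_db <= target_M_db)[0]
        if below.size == 0:
            return math.inf
        i = below[0]
        if i == 0:
            return float(self.t[0])
        t0, t1 = self.t[i - 1], self.t[i]
        m0, m1 = self.M_db[i - 1], self.M_db[i]
        return float(t0 + (m0 - target_M_db) / (m0 - m1) * (t1 - t0))


def _validate_schedule(stages, t_end: float | None = None) -> float:
    if not stages:
        raise ValueError("schedule has no stages")
    prev_end = 0.0
    for st in stages:
        if not math.isclose(st.start, prev_end, abs_tol=1e-9):
            raise ValueError(
                f"schedule stages must tile [0, t_end]: gap/overlap at t={st.start:g}"
            )
        if st.end <= st.start:
            raise ValueError("stage with nonpositive duration")
        prev_end = st.end
    return prev_end


def run(
    schedule,
    grid: Grid | None = None,
    props: MaterialProperties | None = None,
    bounds: BoundarySpec | None = None,
    cfg: SolverConfig | None = None,
    rf: emfield.RFConfig | None = None,
    T_init: float = 22.0,
    w_wb_init: float = 0.796,
) -> SimulationResult:
    """Integrate a drying schedule and record the summary time series.

    ``schedule`` is any object with a ``stages`` attribute (or a plain list)
    of stages carrying ``start``/``end`` (s) and ``rf_on``.  Initial state:
    uniform room temperature and uniform moisture at the given wet-basis
    fraction; the dry-matter density ρ_dm = ρs·(1 − w_wb) is constant
    (no shrinkage).
    """
    grid = grid or Grid()
    props = props or MaterialProperties()
    bounds = bounds or BoundarySpec()
    cfg = cfg or SolverConfig()
    rf = rf or emfield.RFConfig()
    stages = getattr(schedule, "stages", schedule)
    t_end = _validate_schedule(stages)

    rho_dm = props.rho_s * (1.0 - w_wb_init)
    C0 = props.rho_s * w_wb_init  # = rho_dm · M0_db
    state = SimState(
        t=0.0,
        T=np.full((grid.nz, grid.nr), float(T_init)),
        C=np.full((grid.nz, grid.nr), float(C0)),
        rho_dm=rho_dm,
    )
    coupler = _FieldCoupler(rf, props, grid, cfg)

    audit = {
        "water_initial_kg": float(np.sum(state.C * grid.vol)),
        "evaporated_kg": 0.0,
        "conv_in_J": 0.0,
        "evap_out_J": 0.0,
        "rf_in_J": 0.0,
        "stored_J": 0.0,
        "picard_total": 0,
    }

    rec = {k: [] for k in ("t", "Tc", "Ts", "M", "Mc", "rf", "Q")}

    z_mid = 0.5 * grid.thickness

    def record(s: SimState, q_total: float) -> None:
        rec["t"].append(s.t)
        # axis values interpolated to the geometric mid-plane
        rec["Tc"].append(float(np.interp(z_mid, grid.zc, s.T[:, 0])))
        rec["Ts"].append(float(np.sum(s.T[-1, :] * grid.ring_area) / np.sum(grid.ring_area)))
        rec["M"].append(float(np.sum(s.C * grid.vol) / (rho_dm * grid.total_volume)))
        rec["Mc"].append(float(np.interp(z_mid, grid.zc, s.C[:, 0])) / rho_dm)
        rec["rf"].append(s.rf_on)
        rec["Q"].append(q_total)

    record(state, 0.0)
    next_record = cfg.record_every
    n_steps = int(round(t_end / cfg.dt))
    for istep in range(n_steps):
        t_now = state.t
        stage = next(st for st in stages if st.start <= t_now < st.end)
        state.rf_on = bool(stage.rf_on)
        transport = cfg.transport_rf if state.rf_on else cfg.transport_ha
        state, fluxes, stored, n_pic = step_coupled(
            state, grid, props, bounds, cfg, transport, coupler
        )
        audit["conv_in_J"] += fluxes["conv_in_W"] * cfg.dt
        audit["evap_out_J"] += fluxes["evap_out_W"] * cfg.dt
        audit["rf_in_J"] += fluxes["rf_in_W"] * cfg.dt
        audit["stored_J"] += stored
        audit["evaporated_kg"] += fluxes["evap_out_W"] / bounds.h_fg * cfg.dt
        audit["picard_total"] += n_pic
        if state.t >= next_record - 1e-9 or istep == n_steps - 1:
            record(state, fluxes["rf_in_W"])
            next_record += cfg.record_every

    audit["water_final_kg"] = float(np.sum(state.C * grid.vol))
    audit["field_solves"] = coupler.n_solves
    return SimulationResult(
        t=np.asarray(rec["t"]),
        T_center=np.asarray(rec["Tc"]),
        T_surface_mean=np.asarray(rec["Ts"]),
        M_db=np.asarray(rec["M"]),
        M_wb=np.asarray(rec["M"]) / (1.0 + np.asarray(rec["M"])),
        M_db_center=np.asarray(rec["Mc"]),
        rf_on=np.asarray(rec["rf"], bool),
        Q_rf_total_W=np.asarray(rec["Q"]),
        final_state=state,
        audit=audit,
    )
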