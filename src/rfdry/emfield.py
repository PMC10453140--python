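"""Quasi-static RF field between parallel plates and the volumetric heat source.

At 27.12 MHz the wavelength (~11 m) dwarfs the 0.11 m electrode gap, so the
field obeys a complex-coefficient Laplace equation
``−∇·((σ + j·2πf·ε0·ε*)∇V) = 0`` with the top plate at potential V_top and the
bottom plate grounded.  Two solvers are provided:

* :func:`layered_field` — exact series-capacitor solution for a horizontal
  stack of uniform dielectric layers (the default during coupled runs, where
  the single slice is treated as one lossy layer);
* :func:`laplace_2d` — an axisymmetric finite-volume solve on an (r, z) grid
  for arbitrary permittivity/conductivity maps, used to resolve fringing at
  the slice edge and as a cross-check of the layered closed form.

The deposited power density is ``Q_rf = 2πf·ε0·ε″·|E|²`` with |E| an RMS
magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import minimize_scalar

__all__ = [
    "EPS0",
    "Layer",
    "RFConfig",
    "FieldSolution",
    "layered_field",
    "laplace_2d",
    "q_rf",
    "calibrate_voltage",
    "CalibrationResult",
]

EPS0 = 8.854e-12  # vacuum permittivity, F/m


@dataclass(frozen=True)
class Layer:
    """One horizontal slab in the electrode gap."""

    thickness: float  # m
    eps_rel: complex  # ε* = ε′ − j·ε″
    sigma: float = 0.0  # S/m

    def admittivity(self, f: float) -> complex:
        """κ = σ + j·2πf·ε0·ε* (the coefficient of the quasi-static operator)."""
        return self.sigma + 1j * 2.0 * math.pi * f * EPS0 * self.eps_rel


@dataclass
class RFConfig:
    """Electrode geometry and excitation.

    Default layer stack (bottom → top): 20 mm air below the slice (tray
    offset), the 8 mm slice, and 82 mm air above, filling the 110 mm gap.
    The slice permittivity is refreshed from (T, W) during coupled runs.
    """

    f: float = 27.12e6  # Hz
    gap: float = 0.110  # m
    V_top: float = 15e3  # V (calibrated; unpublished in the source study)
    plate_area: float = 0.80 * 0.43  # m²
    air_below: float = 0.020  # m
    sample_thickness: float = 0.008  # m
    layers: list[Layer] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("frequency must be positive")
        if self.layers is not None:
            total = sum(la.thickness for la in self.layers)
            if any(la.thickness <= 0 for la in self.layers):
                raise ValueError("all layer thicknesses must be positive")
            if not math.isclose(total, self.gap, rel_tol=1e-9):
                raise ValueError(
                    f"layer thicknesses sum to {total:g}, not the gap {self.gap:g}"
                )

    def stack_for_sample(self, eps_sample: complex, sigma: float = 0.0) -> list[Layer]:
        """Air / sample / air stack with the given slice permittivity."""
        air_above = self.gap - self.air_below - self.sample_thickness
        if air_above < 0:
            raise ValueError("sample + tray offset exceed the electrode gap")
        return [
            Layer(self.air_below, 1.0 + 0.0j),
            Layer(self.sample_thickness, eps_sample, sigma),
            Layer(air_above, 1.0 + 0.0j),
        ]


@dataclass
class FieldSolution:
    """Potential, field magnitude and volumetric power on an (r, z) grid.

    Arrays are cell-centred, indexed ``[iz, ir]``; ``r``/``z`` give the cell
    centre coordinates in metres.
    """

    r: np.ndarray
    z: np.ndarray
    V: np.ndarray  # complex potential
    E_mag: np.ndarray  # |E|, V/m
    Q_rf: np.ndarray  # W/m³
    residual: float


def layered_field(V_top: float, layers: list[Layer], f: float = 27.12e6) -> np.ndarray:
    """Complex field E_i in each layer of a series dielectric stack.

    Continuity of the normal current density J = κ·E across interfaces gives
    ``E_i = J/κ_i`` with ``J = V_top / Σ_j d_j/κ_j`` (voltage drops sum to
    V_top).  Returned E_i point from the top plate toward ground.
    """
    if not layers:
        raise ValueError("need at least one layer")
    kappas = np.array([la.admittivity(f) for la in layers])
    d = np.array([la.thickness for la in layers])
    if np.any(d <= 0):
        raise ValueError("zero-thickness layer")
    if np.any(kappas == 0):
        raise ValueError("zero-admittivity layer")
    J = V_top / np.sum(d / kappas)
    return J / kappas


def q_rf(E_mag, eps_loss, f: float):
    """Volumetric RF power density Q = 2πf·ε0·ε″·|E|² (W/m³, |E| RMS)."""
    return 2.0 * math.pi * f * EPS0 * np.asarray(eps_loss, float) * np.asarray(E_mag, float) ** 2


def _series_coupling(k1, d1, k2, d2):
    """Per-unit-area conductance of two half-cells in series.

    Exact for piecewise-constant media in 1-D, so a stratified stack whose
    interfaces align with cell faces is reproduced to solver precision.
    """
    return 1.0 / (0.5 * d1 / k1 + 0.5 * d2 / k2)


def laplace_2d(
    r_edges: np.ndarray,
    z_edges: np.ndarray,
    eps_map: np.ndarray,
    sigma_map: np.ndarray | float,
    f: float,
    V_top: float,
) -> FieldSolution:
    """Axisymmetric complex Laplace solve between grounded and driven plates.

    Cell-centred finite volumes on the grid defined by ``r_edges`` (length
    nr+1, starting at 0) and ``z_edges`` (length nz+1, z=0 the grounded plate,
    z=gap the driven plate).  ``eps_map[iz, ir]`` holds ε* = ε′ − j·ε″ per
    cell.  Boundaries: Dirichlet top/bottom, zero normal current at the axis
    and the outer radius.
    """
    r_edges = np.asarray(r_edges, float)
    z_edges = np.asarray(z_edges, float)
    nr = r_edges.size - 1
    nz = z_edges.size - 1
    eps_map = np.broadcast_to(np.asarray(eps_map, complex), (nz, nr))
    sigma_map = np.broadcast_to(np.asarray(sigma_map, float), (nz, nr))
    omega = 2.0 * math.pi * f
    kappa = sigma_map + 1j * omega * EPS0 * eps_map
    if np.any(kappa == 0):
        raise ValueError("zero-admittivity cell")

    rc = 0.5 * (r_edges[:-1] + r_edges[1:])
    zc = 0.5 * (z_edges[:-1] + z_edges[1:])
    dr = np.diff(r_edges)
    dz = np.diff(z_edges)
    # axisymmetric face areas and cell volumes
    ring_area = math.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2)  # horizontal faces
    side_area = 2.0 * math.pi * r_edges[1:-1]  # per unit Δz, at interior radial faces
    vol = ring_area[None, :] * dz[:, None]

    n = nr * nz
    idx = np.arange(n).reshape(nz, nr)
    rows, cols, vals = [], [], []
    rhs = np.zeros(n, complex)
    diag = np.zeros(n, complex)

    def add(conduct, ia, ib):
        # symmetric admittance between two interior cells
        diag[ia] += conduct
        diag[ib] += conduct
        rows.extend([ia, ib])
        cols.extend([ib, ia])
        vals.extend([-conduct, -conduct])

    # radial couplings
    for ir in range(nr - 1):
        kf = _series_coupling(kappa[:, ir], dr[ir], kappa[:, ir + 1], dr[ir + 1])
        g = kf * side_area[ir] * dz
        for iz in range(nz):
            add(g[iz], idx[iz, ir], idx[iz, ir + 1])
    # axial couplings
    for iz in range(nz - 1):
        kf = _series_coupling(kappa[iz, :], dz[iz], kappa[iz + 1, :], dz[iz + 1])
        g = kf * ring_area
        for ir in range(nr):
            add(g[ir], idx[iz, ir], idx[iz + 1, ir])
    # Dirichlet plates: half-cell coupling to fixed potentials
    g_bot = kappa[0, :] * ring_area / (0.5 * dz[0])
    g_top = kappa[-1, :] * ring_area / (0.5 * dz[-1])
    for ir in range(nr):
        diag[idx[0, ir]] += g_bot[ir]  # V=0: no rhs term
        diag[idx[-1, ir]] += g_top[ir]
        rhs[idx[-1, ir]] += g_top[ir] * V_top

    rows.extend(range(n))
    cols.extend(range(n))
    vals.extend(diag)
    A = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    V = spla.spsolve(A, rhs)
    residual = float(np.linalg.norm(A @ V - rhs) / np.linalg.norm(rhs))
    if residual > 1e-8:
        raise RuntimeError(f"field solve did not converge: residual {residual:g}")
    Vg = V.reshape(nz, nr)

    # reconstruct per-cell E from face current densities (D_n continuous):
    # face J = κ_face·ΔV/d, cell E = J/κ_cell — exact for stratified media
    Jz = np.zeros((nz + 1, nr), complex)
    Jz[0, :] = kappa[0, :] * (Vg[0, :] - 0.0) / (0.5 * dz[0]) * -1.0
    Jz[-1, :] = kappa[-1, :] * (V_top - Vg[-1, :]) / (0.5 * dz[-1]) * -1.0
    for iz in range(nz - 1):
        kf = _series_coupling(kappa[iz, :], dz[iz], kappa[iz + 1, :], dz[iz + 1])
        Jz[iz + 1, :] = -kf * (Vg[iz + 1, :] - Vg[iz, :])
    Ez = 0.5 * (Jz[:-1, :] + Jz[1:, :]) / kappa

    Jr = np.zeros((nz, nr + 1), complex)  # zero at axis and outer radius
    for ir in range(nr - 1):
        kf = _series_coupling(kappa[:, ir], dr[ir], kappa[:, ir + 1], dr[ir + 1])
        Jr[:, ir + 1] = -kf * (Vg[:, ir + 1] - Vg[:, ir])
    Er = 0.5 * (Jr[:, :-1] + Jr[:, 1:]) / kappa

    E_mag = np.sqrt(np.abs(Er) ** 2 + np.abs(Ez) ** 2)
    Q = q_rf(E_mag, -eps_map.imag, f) + sigma_map * E_mag**2
    sol = FieldSolution(r=rc, z=zc, V=Vg, E_mag=E_mag, Q_rf=Q, residual=residual)
    sol.cell_volumes = vol  # type: ignore[attr-defined]
    # top-plate complex current (into the medium), for circuit consistency
    sol.plate_current = np.sum(-Jz[-1, :] * ring_area)  # type: ignore[attr-defined]
    return sol


@dataclass(frozen=True)
class CalibrationResult:
    V_top: float
    objective: float
    n_evaluations: int


def calibrate_voltage(
    objective,
    bounds: tuple[float, float],
    xtol_rel: float = 1e-4,
) -> CalibrationResult:
    """Bracketed scalar search for the electrode voltage.

    ``objective(V)`` returns the discrepancy (e.g. summed squared residuals of
    moisture and centre temperature) between a simulated run at voltage ``V``
    and a reference curve.  Mirrors the trial-and-error plate-voltage tuning
    used to match predictions to measurements.  Raises if the objective is
    insensitive to V (RF never on) or if the minimum sits on the bracket edge.
    """
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("bounds must satisfy lo < hi")
    evals = [0]

    def f(v):
        evals[0] += 1
        return objective(v)

    f_lo, f_mid, f_hi = f(lo), f(0.5 * (lo + hi)), f(hi)
    if f_lo == f_mid == f_hi:
        raise ValueError(
            "objective is independent of V_top (is RF off in this scenario?)"
        )
    res = minimize_scalar(
        f, bounds=(lo, hi), method="bounded",
        options={"xatol": xtol_rel * (hi - lo)},
    )
    edge_tol = 1e-3 * (hi - lo)
    if res.x - lo < edge_tol or hi - res.x < edge_tol:
        raise ValueError(
            f"minimum at bracket edge (V={res.x:g}); widen bounds {bounds}"
        )
    return CalibrationResult(V_top=float(res.x), objective=float(res.fun),
                             n_evaluations=evals[0])
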