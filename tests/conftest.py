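"""Shared fixtures and independent analytic oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from rfdry.properties import MaterialProperties
from rfdry.solver import BoundarySpec, FaceBC, Grid, SimState


@pytest.fixture
def default_props() -> MaterialProperties:
    return MaterialProperties()


@pytest.fixture
def constant_props() -> MaterialProperties:
    """Constant-coefficient material (Cp = 2 kJ/kg/K, k = 0.5 W/m/K)."""
    return MaterialProperties(
        cp_coeffs=(0.0, 0.0, 2.0),
        k_coeffs=(0.0, 0.0, 0.5),
        cp_floor=0.1,
        k_floor=0.01,
    )


@pytest.fixture
def slab_grid() -> Grid:
    """Fine 1-D-like grid (uniform in r once side faces are insulated)."""
    return Grid(nr=4, nz=40)


def uniform_state(grid: Grid, T: float, C: float, rho_dm: float = 224.4) -> SimState:
    return SimState(
        0.0,
        np.full((grid.nz, grid.nr), float(T)),
        np.full((grid.nz, grid.nr), float(C)),
        rho_dm,
    )


def insulated_side_bounds(**kw) -> BoundarySpec:
    kw.setdefault("side", FaceBC(False, False))
    return BoundarySpec(**kw)


def conduction_series(z, t, L, alpha, Bi, T0, T_air, n_terms=20):
    """Transient 1-D slab, insulated at z=0, convective (Robin) at z=L.

    Separation-of-variables series: eigenvalues λn solve λ·tan λ = Bi;
    θ/θ0 = Σ Cn·exp(−λn²·Fo)·cos(λn·z/L) with
    Cn = 4·sin λn / (2λn + sin 2λn).  Independent of the finite-volume path.
    """
    roots = []
    for n in range(n_terms):
        lo = n * math.pi + 1e-12
        hi = n * math.pi + math.pi / 2 - 1e-12
        roots.append(brentq(lambda lam: lam * math.tan(lam) - Bi, lo, hi))
    lam = np.array(roots)
    Cn = 4.0 * np.sin(lam) / (2.0 * lam + np.sin(2.0 * lam))
    z = np.atleast_1d(np.asarray(z, float))
    Fo = alpha * t / L**2
    theta = (Cn * np.exp(-(lam**2) * Fo))[None, :] * np.cos(
        lam[None, :] * z[:, None] / L
    )
    return T_air + (T0 - T_air) * theta.sum(axis=1)


def slab_series_mr(tau, n_terms=20):
    """Mean moisture ratio of a slab at zero surface resistance.

    Full eigenseries MR = Σ (8/π²)/(2k+1)² · exp(−(2k+1)²·π²·τ) with
    τ = D·t/(4L²) for one-sided drying of a slab of thickness L.
    """
    tau = np.asarray(tau, float)
    out = np.zeros_like(tau)
    for k in range(n_terms):
        m = 2 * k + 1
        out = out + 8.0 / (math.pi**2 * m**2) * np.exp(-(m**2) * math.pi**2 * tau)
    return out
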