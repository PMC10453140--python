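"""Drying-kinetics estimators: moisture ratio, lag-factor model, Biot number,
effective diffusivity and the transfer coefficients.

The falling-rate drying of a slab is summarised by the exponential lag model
``MR(t) = Lf·exp(−S·t)``.  The lag factor Lf maps to the mass Biot number
through ``Lf = exp(0.2533·Bi/(1.3+Bi))``; the first eigenvalue of the slab
characteristic equation is approximated explicitly by
``μ₁ = atan(0.640443·Bi + 0.380397)`` (π/2 for Bi ≥ 100).  Diffusivity and the
mass-transfer coefficient follow as ``D = S·L²/μ₁²`` and ``h_m = Bi·D/L`` with
L the diffusion half-thickness.  The convective heat-transfer coefficient uses
the laminar flat-plate correlation ``Nu = 0.664·Re^0.5·Pr^0.33``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .properties import AirProperties

__all__ = [
    "DryingCurve",
    "DincerFit",
    "moisture_ratio",
    "dry_basis",
    "wet_basis",
    "fit_lag_model",
    "biot_from_lag",
    "mu1_from_biot",
    "lag_from_biot",
    "diffusivity_dincer",
    "mass_transfer_coeff",
    "eff_diffusivity_slope",
    "heat_transfer_coeff",
    "fit_dincer",
]

logger = logging.getLogger(__name__)

#: Lf → Bi inversion is finite only below exp(0.2533) (the Bi → ∞ limit)
LF_MAX = math.exp(0.2533)


@dataclass
class DryingCurve:
    """A measured (or simulated) drying curve in dry-basis moisture content.

    ``times`` in seconds, strictly increasing from 0; ``M_db`` in kg water per
    kg dry matter.  ``M0_db``/``Me_db`` default to the first sample and 0.
    """

    times: np.ndarray
    M_db: np.ndarray
    M0_db: float | None = None
    Me_db: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.M_db = np.asarray(self.M_db, float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("need at least 2 time points")
        if self.times.shape != self.M_db.shape:
            raise ValueError("times and M_db must have the same length")
        if self.times[0] != 0.0:
            raise ValueError("times must start at 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.M_db < 0):
            raise ValueError("M_db must be nonnegative")
        if self.M0_db is None:
            self.M0_db = float(self.M_db[0])

    def moisture_ratio(self) -> np.ndarray:
        return moisture_ratio(self.M_db, self.Me_db, self.M0_db)


@dataclass(frozen=True)
class DincerFit:
    """Fitted lag-model kinetics and derived transfer parameters."""

    Lf: float  # lag factor, dimensionless
    S: float  # drying coefficient, s⁻¹
    Bi: float  # mass Biot number
    mu1: float  # first slab eigenvalue, rad
    D: float  # effective moisture diffusivity, m²/s
    hm: float  # mass-transfer coefficient, m/s
    r_squared: float  # R² of the log-linear fit


def moisture_ratio(Mt_db, Me_db, M0_db):
    """MR = (Mt − Me)/(M0 − Me); requires M0 > Me."""
    if M0_db <= Me_db:
        raise ValueError(
            f"degenerate curve: M0_db={M0_db:g} must exceed Me_db={Me_db:g}"
        )
    return (np.asarray(Mt_db, float) - Me_db) / (M0_db - Me_db)


def _check_masses(Wt, Wd) -> None:
    if Wd <= 0:
        raise ValueError("dry mass Wd must be positive")
    if Wt < Wd:
        raise ValueError("total mass Wt cannot be below dry mass Wd")


def dry_basis(Wt: float, Wd: float) -> float:
    """Dry-basis moisture content (%) = (Wt − Wd)/Wd · 100."""
    _check_masses(Wt, Wd)
    return (Wt - Wd) / Wd * 100.0


def wet_basis(Wt: float, Wd: float) -> float:
    """Wet-basis moisture content (%) = (Wt − Wd)/Wt · 100."""
    _check_masses(Wt, Wd)
    return (Wt - Wd) / Wt * 100.0


def fit_lag_model(curve: DryingCurve) -> tuple[float, float, float]:
    """Fit MR = Lf·exp(−S·t) by least squares on ln MR vs t.

    Points with MR ≤ 0 (possible under measurement noise near equilibrium)
    are excluded with a warning.  Returns ``(Lf, S, r_squared)``.
    """
    mr = curve.moisture_ratio()
    keep = mr > 0
    if np.any(~keep):
        logger.warning(
            "fit_lag_model: excluding %d points with MR <= 0", int(np.sum(~keep))
        )
    if np.sum(keep) < 3:
        raise ValueError("need at least 3 points with MR > 0")
    t = curve.times[keep]
    y = np.log(mr[keep])
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return float(np.exp(intercept)), float(-slope), r2


def lag_from_biot(Bi: float) -> float:
    """Forward map Lf = exp(0.2533·Bi/(1.3 + Bi))."""
    if Bi < 0:
        raise ValueError("Bi must be nonnegative")
    return math.exp(0.2533 * Bi / (1.3 + Bi))


def biot_from_lag(Lf: float) -> float:
    """Invert Lf = exp(0.2533·Bi/(1.3+Bi)): Bi = 1.3·ln Lf/(0.2533 − ln Lf).

    Lf ≤ 1 returns the Bi = 0 boundary with a warning; Lf ≥ exp(0.2533)
    is outside the model (it is the Bi → ∞ asymptote).
    """
    if Lf >= LF_MAX:
        raise ValueError(
            f"Lf={Lf:g} ≥ exp(0.2533)={LF_MAX:.6f}: outside the lag model"
        )
    if Lf <= 1.0:
        logger.warning("biot_from_lag: Lf=%g ≤ 1, returning Bi=0 boundary", Lf)
        return 0.0
    ln_lf = math.log(Lf)
    return 1.3 * ln_lf / (0.2533 - ln_lf)


def mu1_from_biot(Bi: float) -> float:
    """First slab eigenvalue μ₁(Bi): π/2 for Bi ≥ 100, else the explicit
    approximation atan(0.640443·Bi + 0.380397)."""
    if Bi < 0:
        raise ValueError("Bi must be nonnegative")
    if Bi >= 100.0:
        return math.pi / 2.0
    return math.atan(0.640443 * Bi + 0.380397)


def diffusivity_dincer(S: float, L_half: float, mu1: float) -> float:
    """D = S·L_half²/μ₁² (L_half = diffusion half-thickness, m)."""
    if L_half <= 0 or mu1 <= 0:
        raise ValueError("L_half and mu1 must be positive")
    return S * L_half**2 / mu1**2


def mass_transfer_coeff(Bi: float, D: float, L_half: float) -> float:
    """h_m = Bi·D/L_half, m/s."""
    if L_half <= 0:
        raise ValueError("L_half must be positive")
    return Bi * D / L_half


def fit_dincer(curve: DryingCurve, L_half: float) -> DincerFit:
    """Full pipeline: lag fit → Bi → μ₁ → D → h_m."""
    Lf, S, r2 = fit_lag_model(curve)
    Bi = biot_from_lag(Lf)
    mu1 = mu1_from_biot(Bi)
    D = diffusivity_dincer(S, L_half, mu1)
    hm = mass_transfer_coeff(Bi, D, L_half)
    return DincerFit(Lf=Lf, S=S, Bi=Bi, mu1=mu1, D=D, hm=hm, r_squared=r2)


def eff_diffusivity_slope(
    curve: DryingCurve,
    L_char: float,
    fit_slice: slice = slice(None),
) -> float:
    """Effective diffusivity from the slope method.

    On the falling-rate portion the first term of the slab series dominates:
    MR ≈ (8/π²)·exp(−π²·D_eff·t/(4·L²)), so the slope of ln MR vs t gives
    D_eff = −slope·4L²/π².  ``fit_slice`` selects the late-time window.
    ``L_char`` is the slab thickness for one-sided drying (impermeable base),
    or the half-thickness for symmetric two-sided drying.
    """
    if L_char <= 0:
        raise ValueError("L_char must be positive")
    mr = curve.moisture_ratio()[fit_slice]
    t = curve.times[fit_slice]
    keep = mr > 0
    if np.sum(keep) < 3:
        raise ValueError("need at least 3 points with MR > 0 in fit window")
    slope = np.polyfit(t[keep], np.log(mr[keep]), 1)[0]
    if slope >= 0:
        raise ValueError("curve not drying: nonnegative ln MR slope")
    return float(-slope * 4.0 * L_char**2 / math.pi**2)


def heat_transfer_coeff(v: float, L_char: float, air: AirProperties) -> float:
    """Convective heat-transfer coefficient from the laminar flat-plate
    correlation: Re = ρa·v·L/μa, Pr = Cpa·μa/ka, Nu = 0.664·Re^0.5·Pr^0.33,
    h_T = Nu·ka/L.  Warns beyond the laminar validity (Re > 5e5)."""
    if v < 0 or L_char <= 0:
        raise ValueError("need v ≥ 0 and L_char > 0")
    Re = air.rho_a * v * L_char / air.mu_a
    if Re > 5e5:
        logger.warning("heat_transfer_coeff: Re=%g beyond laminar validity", Re)
    Pr = air.prandtl
    Nu = 0.664 * Re**0.5 * Pr**0.33
    return Nu * air.k_a / L_char
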