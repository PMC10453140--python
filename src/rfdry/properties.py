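"""Material and air property models for jujube-slice drying.

All tissue properties are bilinear (or bilinear-with-interaction) regressions
in temperature ``T`` (°C) and wet-basis moisture fraction ``W`` (0-1), fitted
to DSC, dual-needle probe and open-coaxial-probe measurements at 27.12 MHz:

* specific heat        Cp  = 0.043·T + 1.047·W − 1.333          [kJ·kg⁻¹·K⁻¹]
* thermal conductivity k   = 0.008·T + 0.675·W − 0.261          [W·m⁻¹·K⁻¹]
* dielectric constant  ε′  = 34.519·W + 0.072·T + 46.022        [-]
* loss factor          ε″  = 319.028·W + 1.150·T + 3.786·W·T + 46.952  [-]

The linear Cp/k fits go negative far below the measured moisture range, so
evaluated values are clamped at small positive floors typical of dry plant
solids (0.85 kJ·kg⁻¹·K⁻¹, 0.05 W·m⁻¹·K⁻¹); ε′ and ε″ are positive on the whole
validity domain and are not clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialProperties",
    "AirProperties",
    "air_properties",
    "latent_heat",
    "concentration_from_moisture",
    "moisture_from_concentration",
    "wet_basis_fraction",
]

#: default regression coefficients, exactly as fitted
CP_COEFFS = (0.043, 1.047, -1.333)
K_COEFFS = (0.008, 0.675, -0.261)
EPS_PRIME_COEFFS = (34.519, 0.072, 46.022)
EPS_LOSS_COEFFS = (319.028, 1.150, 3.786, 46.952)


class ValidityError(ValueError):
    """An input lies outside the property-regression validity domain."""


def _check_range(name: str, value, lo: float, hi: float) -> None:
    value = np.asarray(value, dtype=float)
    if np.any(value < lo) or np.any(value > hi):
        bad = float(np.min(value)) if np.any(value < lo) else float(np.max(value))
        raise ValidityError(
            f"{name}={bad:g} outside validity range [{lo:g}, {hi:g}]"
        )


@dataclass
class MaterialProperties:
    """Temperature- and moisture-dependent tissue properties.

    Parameters
    ----------
    cp_coeffs, k_coeffs, eps_prime_coeffs, eps_loss_coeffs
        Regression coefficients; defaults are the fitted values above.
    rho_s
        Bulk density of the wet tissue, kg/m³ (constant: no shrinkage).
    sigma
        Ionic electrical conductivity, S/m.  With the default 0 the
        quasi-static field operator is purely dielectric.
    Me
        Equilibrium dry-basis moisture content, kg water per kg dry matter.
    cp_floor, k_floor
        Positive clamping floors for the linear Cp/k fits.
    T_range, W_range
        Validity window for the regressions (°C and wet-basis fraction).
    """

    cp_coeffs: tuple = CP_COEFFS
    k_coeffs: tuple = K_COEFFS
    eps_prime_coeffs: tuple = EPS_PRIME_COEFFS
    eps_loss_coeffs: tuple = EPS_LOSS_COEFFS
    rho_s: float = 1100.0
    sigma: float = 0.0
    Me: float = 0.05
    cp_floor: float = 0.85
    k_floor: float = 0.05
    T_range: tuple = (15.0, 100.0)
    W_range: tuple = (0.0, 0.9)
    validate_inputs: bool = True

    def __post_init__(self) -> None:
        if self.rho_s <= 0:
            raise ValueError("rho_s must be positive")
        if self.Me < 0:
            raise ValueError("Me must be nonnegative")

    def _validate(self, T, W) -> None:
        if self.validate_inputs:
            _check_range("T", T, *self.T_range)
            _check_range("W", W, *self.W_range)

    def specific_heat(self, T, W):
        """Specific heat Cp(T, W) in kJ·kg⁻¹·K⁻¹, clamped below at cp_floor."""
        self._validate(T, W)
        a, b, c = self.cp_coeffs
        raw = a * np.asarray(T, float) + b * np.asarray(W, float) + c
        return np.maximum(raw, self.cp_floor)

    def specific_heat_J(self, T, W):
        """Cp in J·kg⁻¹·K⁻¹ (SI, as the heat equation needs)."""
        return 1e3 * self.specific_heat(T, W)

    def thermal_conductivity(self, T, W):
        """Thermal conductivity k(T, W) in W·m⁻¹·K⁻¹, clamped at k_floor."""
        self._validate(T, W)
        a, b, c = self.k_coeffs
        raw = a * np.asarray(T, float) + b * np.asarray(W, float) + c
        return np.maximum(raw, self.k_floor)

    def dielectric_constant(self, T, W):
        """Relative dielectric constant ε′(T, W) at 27.12 MHz."""
        self._validate(T, W)
        a, b, c = self.eps_prime_coeffs
        return a * np.asarray(W, float) + b * np.asarray(T, float) + c

    def loss_factor(self, T, W):
        """Dielectric loss factor ε″(T, W) at 27.12 MHz."""
        self._validate(T, W)
        a, b, c, d = self.eps_loss_coeffs
        T = np.asarray(T, float)
        W = np.asarray(W, float)
        return a * W + b * T + c * W * T + d

    def complex_permittivity(self, T, W):
        """ε* = ε′ − j·ε″ (loss convention: negative imaginary part)."""
        return self.dielectric_constant(T, W) - 1j * self.loss_factor(T, W)


@dataclass(frozen=True)
class AirProperties:
    """Dry-air transport properties at a stated temperature."""

    rho_a: float  # kg/m³
    mu_a: float  # Pa·s
    cp_a: float  # J·kg⁻¹·K⁻¹
    k_a: float  # W·m⁻¹·K⁻¹
    T_air: float = field(default=60.0)  # °C

    def __post_init__(self) -> None:
        for name in ("rho_a", "mu_a", "cp_a", "k_a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def prandtl(self) -> float:
        return self.cp_a * self.mu_a / self.k_a


# dry air at 101.325 kPa: ideal-gas density; Sutherland viscosity;
# near-constant cp; linear conductivity fit to standard tables (0-150 °C)
_R_AIR = 287.058  # J·kg⁻¹·K⁻¹
_P_ATM = 101325.0  # Pa


def air_properties(T_air: float) -> AirProperties:
    """Dry-air ρ, μ, Cp, k at ``T_air`` °C and 1 atm.

    Density from the ideal-gas law; viscosity from Sutherland's formula
    (μ_ref = 1.716e-5 Pa·s at 273.15 K, S = 110.4 K); conductivity from a
    linear fit k = 0.0241 + 7.8e-5·T to tabulated dry-air data; Cp = 1007.
    """
    if not 0.0 <= T_air <= 150.0:
        raise ValueError(f"T_air={T_air:g} outside supported range [0, 150] °C")
    TK = T_air + 273.15
    rho = _P_ATM / (_R_AIR * TK)
    mu = 1.716e-5 * (TK / 273.15) ** 1.5 * (273.15 + 110.4) / (TK + 110.4)
    k = 0.0241 + 7.8e-5 * T_air
    return AirProperties(rho_a=rho, mu_a=mu, cp_a=1007.0, k_a=k, T_air=T_air)


def latent_heat(T) -> float:
    """Latent heat of evaporation of water, J/kg, h_fg = 2.503e6 − 2386·T(°C)."""
    return 2.503e6 - 2386.0 * np.asarray(T, float)


def concentration_from_moisture(M_db, rho_dm: float):
    """Moisture concentration C (kg water / m³ tissue) from dry-basis content.

    ``rho_dm`` is dry-matter mass per unit total volume (kg/m³), constant
    under the no-shrinkage assumption: C = rho_dm · M_db.
    """
    if rho_dm <= 0:
        raise ValueError("rho_dm must be positive")
    M_db = np.asarray(M_db, float)
    if np.any(M_db < 0):
        raise ValueError("M_db must be nonnegative")
    return rho_dm * M_db


def moisture_from_concentration(C, rho_dm: float):
    """Inverse of :func:`concentration_from_moisture` (exact)."""
    if rho_dm <= 0:
        raise ValueError("rho_dm must be positive")
    return np.asarray(C, float) / rho_dm


def wet_basis_fraction(M_db):
    """Wet-basis moisture fraction W = M_db / (1 + M_db)."""
    M_db = np.asarray(M_db, float)
    return M_db / (1.0 + M_db)
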