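"""Drying scenarios, model-vs-reference comparison metrics, and
pseudo-experimental fixture generation.

The 4.5 h hot-air process (60 °C, 2.5 m/s) is split into three equal 1.5 h
stages; RF is applied during exactly one of them:

* ``HA``        — hot air only,
* ``E-HA+RF``   — RF during the early stage [0, 1.5 h),
* ``M-HA+RF``   — RF during the middle stage [1.5, 3 h),
* ``L-HA+RF``   — RF during the late stage [3, 4.5 h).

Comparison against a reference curve reports R² (about the reference mean),
RMSE and the extreme absolute differences, with the simulated series
interpolated onto the reference time points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import solver as _solver
from .emfield import RFConfig
from .properties import MaterialProperties
from .solver import BoundarySpec, Grid, SolverConfig, SimulationResult

__all__ = [
    "Stage",
    "DryingSchedule",
    "SCENARIOS",
    "make_schedule",
    "ComparisonReport",
    "compare",
    "simulate_scenario",
    "make_fixture",
]

T_END_DEFAULT = 16200.0  # 4.5 h in seconds
SCENARIOS = ("HA", "E-HA+RF", "M-HA+RF", "L-HA+RF")


@dataclass(frozen=True)
class Stage:
    start: float  # s
    end: float  # s
    rf_on: bool


@dataclass
class DryingSchedule:
    name: str
    stages: list[Stage]

    def __post_init__(self) -> None:
        _solver._validate_schedule(self.stages)

    @property
    def t_end(self) -> float:
        return self.stages[-1].end


def make_schedule(name: str, t_end: float = T_END_DEFAULT) -> DryingSchedule:
    """Canonical three-stage schedule for a named scenario."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; valid names: {list(SCENARIOS)}")
    third = t_end / 3.0
    rf_stage = {"HA": None, "E-HA+RF": 0, "M-HA+RF": 1, "L-HA+RF": 2}[name]
    stages = [
        Stage(i * third, (i + 1) * third, rf_on=(i == rf_stage)) for i in range(3)
    ]
    return DryingSchedule(name=name, stages=stages)


@dataclass(frozen=True)
class ComparisonReport:
    r_squared: float
    max_abs_diff: float
    min_abs_diff: float
    rmse: float
    n_points: int


def compare(sim_t, sim_y, ref_t, ref_y) -> ComparisonReport:
    """Goodness of fit of a simulated series against a reference series.

    The simulation is linearly interpolated onto the reference time points
    (restricted to the overlapping window).  R² = 1 − SS_res/SS_tot with
    SS_tot about the reference mean — note R² is not symmetric under
    exchanging the two series, while max/min/RMSE are.
    """
    sim_t = np.asarray(sim_t, float)
    sim_y = np.asarray(sim_y, float)
    ref_t = np.asarray(ref_t, float)
    ref_y = np.asarray(ref_y, float)
    inside = (ref_t >= sim_t[0]) & (ref_t <= sim_t[-1])
    t, y_ref = ref_t[inside], ref_y[inside]
    if t.size < 3:
        raise ValueError("need at least 3 shared time points")
    y_sim = np.interp(t, sim_t, sim_y)
    resid = y_sim - y_ref
    ss_tot = float(np.sum((y_ref - y_ref.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("constant reference series: R² undefined")
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    ad = np.abs(resid)
    return ComparisonReport(
        r_squared=r2,
        max_abs_diff=float(ad.max()),
        min_abs_diff=float(ad.min()),
        rmse=float(math.sqrt(np.mean(resid**2))),
        n_points=int(t.size),
    )


def simulate_scenario(
    name: str,
    grid: Grid | None = None,
    props: MaterialProperties | None = None,
    bounds: BoundarySpec | None = None,
    cfg: SolverConfig | None = None,
    rf: RFConfig | None = None,
    t_end: float = T_END_DEFAULT,
    **run_kwargs,
) -> SimulationResult:
    """Run one canonical scenario with (optionally overridden) defaults."""
    schedule = make_schedule(name, t_end=t_end)
    return _solver.run(
        schedule, grid=grid, props=props, bounds=bounds, cfg=cfg, rf=rf, **run_kwargs
    )


def make_fixture(
    scenario: str,
    noise_sigma_M: float = 0.0,
    noise_sigma_T: float = 0.0,
    seed: int = 0,
    sample_every: float = 1800.0,
    **sim_kwargs,
):
    """Pseudo-experimental reference curves: simulation output plus seeded
    Gaussian noise, sampled at the measurement cadence (default 30 min).

    Synthetic stand-in for unavailable measured drying curves.  Returns a
    DataFrame with columns t_s, M_db, T_center_C, T_surface_mean_C;
    deterministic for a given seed.
    """
    import pandas as pd

    result = simulate_scenario(scenario, **sim_kwargs)
    rng = np.random.default_rng(seed)
    t_ref = np.arange(0.0, result.t[-1] + 1e-9, sample_every)
    M = np.interp(t_ref, result.t, result.M_db)
    Tc = np.interp(t_ref, result.t, result.T_center)
    Ts = np.interp(t_ref, result.t, result.T_surface_mean)
    if noise_sigma_M > 0:
        M = np.clip(M + rng.normal(0.0, noise_sigma_M, M.shape), 0.0, None)
    if noise_sigma_T > 0:
        Tc = Tc + rng.normal(0.0, noise_sigma_T, Tc.shape)
        Ts = Ts + rng.normal(0.0, noise_sigma_T, Ts.shape)
    return pd.DataFrame(
        {"t_s": t_ref, "M_db": M, "T_center_C": Tc, "T_surface_mean_C": Ts}
    )
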