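# Methods

## Physical model

The slice is a cylinder (R = 15 mm, H = 8 mm) of homogeneous, isotropic
tissue resting on a polypropylene tray between the plates of a 27.12 MHz RF
applicator (gap 110 mm, slice bottom 20 mm above the grounded plate) in
60 °C, 2.5 m/s air. Moisture is assumed to move as liquid by Fickian
diffusion down the concentration gradient; evaporation happens only at the
exposed surface; the geometry does not shrink. Under those assumptions the
interior model is

- heat: ρs·Cp(T,W)·∂T/∂t = ∇·(k(T,W)∇T) + Q_rf,
- moisture: ∂C/∂t = ∇·(D_eff∇C), with C = ρ_dm·M_db the liquid-water
  concentration (kg/m³) and ρ_dm = ρs·(1 − w_wb,0) the (constant) dry-matter
  density.

A convective term sometimes written inside the energy balance of porous-food
models is omitted: there is no internal airflow through intact tissue, and
the coefficient (an air viscosity) cannot multiply a temperature gradient
dimensionally. The interior is conduction plus the RF source.

Boundary faces combine a convective gain with an evaporative sink tied to
the moisture outflux:

- k∇T·n = h_T·(T_air − T_s) − h_fg·h_m·(C_s − C_eq),
- −D_eff∇C·n = h_m·(C_s − C_eq).

C_eq = ρ_dm·Me is the surface concentration in equilibrium with the drying
air; outflux stops when the surface reaches it. Face roles: top = convective
+ evaporative; rim = convective heat only; tray face = adiabatic and
impermeable (one-sided drying). With one-sided drying, the 8 mm slab is
diffusively equivalent to half of a symmetric 16 mm slab, so the slope-method
characteristic length is the full thickness while the lag-model inversions
use the 4 mm half-thickness.

## RF field and heating

At 27.12 MHz the free-space wavelength (~11 m) dwarfs the 110 mm gap, so the
potential obeys the quasi-static complex Laplace equation
−∇·((σ + j·2πf·ε0·ε*)∇V) = 0 with ε* = ε′ − j·ε″, V = V_top on the driven
plate and V = 0 on the ground plate. Two solvers:

- layered (default for coupled runs): the gap is a series stack
  air (20 mm) / slice (8 mm) / air (82 mm); continuity of normal current
  density gives E_i = V_top/(κ_i·Σ_j d_j/κ_j) per layer in closed form. The
  slice permittivity is evaluated at the volume-mean (T, W).
- 2-D axisymmetric finite volumes for arbitrary (r, z) permittivity maps
  (fringing at the slice rim), with zero normal current on the axis and the
  open radial boundary. Face conductances chain the two half-cells in
  series, which reproduces a horizontally stratified stack to solver
  precision when interfaces align with faces.

Deposited power density is Q_rf = 2πf·ε0·ε″·|E|² (|E| an RMS magnitude),
plus σ|E|² when an ionic conductivity is configured (default σ = 0). The
field is re-solved only when the state has drifted (max |ΔT| > 0.5 °C or
max |ΔM_db| > 0.05 since the last solve) because the permittivity responds
slowly; the cadence is configurable.

The plate voltage is not generally known for an RF dryer; it is recovered by
a bracketed scalar search minimising the squared mismatch of moisture and
centre-temperature histories against a reference run (`calibrate_voltage`).
The default V_top = 15 kV was chosen by that same procedure so that
late-stage RF produces a surface-temperature rise of the ~15–20 °C magnitude
reported for this process class; it is a configuration key, not a fitted
constant of the model.

## Material properties

Bilinear regressions in T (°C) and wet-basis moisture fraction W (0–1),
valid on T ∈ [15, 100], W ∈ [0, 0.9]:

| quantity | expression | units |
|---|---|---|
| Cp | 0.043·T + 1.047·W − 1.333 | kJ·kg⁻¹·K⁻¹ |
| k | 0.008·T + 0.675·W − 0.261 | W·m⁻¹·K⁻¹ |
| ε′ | 34.519·W + 0.072·T + 46.022 | – |
| ε″ | 319.028·W + 1.150·T + 3.786·W·T + 46.952 | – |

W here is a fraction: with that reading the evaluated ε′ exceeds 70 for wet
tissue, matching the near-water behaviour expected of high-moisture fruit.
The linear Cp/k fits go negative far outside the measured moisture range, so
evaluated values are clamped at floors typical of dry plant solids
(0.85 kJ·kg⁻¹·K⁻¹ and 0.05 W·m⁻¹·K⁻¹); the solver additionally clips the
(T, W) at which it evaluates properties to the validity window. Bulk density
defaults to 1100 kg/m³ and the equilibrium moisture to Me = 0.05 kg/kg db —
neither is pinned by measurement here; both are configuration keys. Air
properties come from the ideal-gas law, Sutherland viscosity, Cp = 1007
J·kg⁻¹·K⁻¹ and a linear conductivity fit to dry-air tables, evaluated at the
bulk air temperature (not the film temperature — the simplest consistent
reading of the flat-plate correlation's inputs); latent heat uses the linear
water correlation h_fg = 2.503e6 − 2386·T.

## Discretisation and numerics

Cell-centred finite volumes on a uniform axisymmetric grid (default
10 radial × 8 axial cells; exact ring areas and volumes, so cell volumes sum
to πR²H to round-off). Time stepping is backward Euler at dt = 1 s with
Picard lagging of Cp(T,W) and k(T,W): the moisture step (independent of T
when the Arrhenius hook is off) is solved once per step, then the heat step
iterates property evaluation until max |ΔT| < 1e-3 °C (typically 2
iterations; hard failure advises a smaller step). Boundary exchange chains
the film coefficient with the half-cell conduction path,
U = 1/(1/h + δ/(2k_cell)), which keeps the discrete Robin condition accurate
on coarse grids. Because the scheme is conservative and the audits use the
same discrete fluxes as the matrices, the mass and energy budgets close to
solver precision (~1e-15 relative); the audit is a guard against coding and
coupling errors, not a tuned tolerance.

Tolerance defaults (tol_T = 1e-3 °C, tol_C = 1e-6 relative) are much
stricter than the loose relative tolerance a general-purpose FEM package
would accept for this problem, because the conservation audits are part of
the deliverable. Discretisation error at the defaults, measured by
self-convergence over the full 4.5 h horizon: halving dt moves the
centre-temperature trajectory by < 0.03 °C; doubling both grid counts moves
the final centre temperature by < 0.2 °C (the largest transient excursion
between resolutions, mid-RF, is ~1 °C).

## Drying schedules and stage-wise kinetics

The 4.5 h process divides into three equal stages; RF is on during none
(HA), the first (E-HA+RF), second (M-HA+RF) or third (L-HA+RF). D_eff and
h_m are held constant within a stage, with separate HA-stage and RF-stage
values — the constant-per-stage reading of falling-rate drying behind the
Dincer method. The HA defaults (D_eff = 6.25e-9 m²/s, h_m = 1.56e-6 m/s)
were derived a priori from the lag-model algebra: Bi = 2 and the requirement
that the mean moisture reach the 1.0 kg/kg db target shortly before the end
of the 4.5 h window, matching the qualitative endpoint of hot-air drying of
8 mm slices at 60 °C. RF-stage values are 1.6× the HA values, representing
the faster moisture migration under volumetric heating; the temperature
consequences of RF (centre > surface, later-stage peaks higher) emerge from
the field–property coupling, not from these constants.

## Synthetic references

`make_fixture` stands in for measured drying/temperature curves, which are
not published as data: it samples a simulation at the 30 min weighing cadence
and adds seeded Gaussian noise. Fixtures therefore share the simulator's
physics by construction — agreement between a run and its fixture
demonstrates the comparison and calibration machinery (interpolation, R²,
voltage search), not experimental validity. What passing tests do show: the
solvers agree with independent analytic series solutions; conservation holds;
the estimator loops invert their own forward models under realistic noise;
and the qualitative RF-staging fingerprints reported for this process are
reproduced at default settings.

## Problem sizes used in validation

The analytic-oracle checks use a 40-cell axial grid (dt = 0.05 s for the
600 s conduction transient; dt = 5 s for the 5.5 h diffusion decay). The
voltage-calibration loops run a reduced scenario (30 min RF window, 4×4
grid, dt = 30 s) so that one objective evaluation costs ~0.1 s and the
noisy Monte-Carlo (100 calibrations) stays cheap; noiseless recovery is
~0.002%, so the reduction does not mask bias. Scenario-level checks run the
full 4.5 h at the default resolution.

## Known limitations

- No shrinkage, no porosity evolution, no internal vapour-pressure transport;
  late-stage drying of real fruit departs from the constant-D Fickian
  picture.
- The layered field mode ignores fringing at the slice rim (available via
  the 2-D mode) and treats the slice permittivity as uniform at the mean
  state.
- The tray's permittivity is neglected (thin, low-loss); extension point in
  the layer stack.
- Lag-model inversion applies to the centre-point moisture history; mean
  moisture curves of one-sided slabs have intercepts ≤ 1 and then return the
  Bi → 0 boundary with a warning rather than a spurious fit.
- Property regressions are extrapolated (clamped) outside the measured
  window; behaviour above ~100 °C or below ~15 °C is not meaningful.
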