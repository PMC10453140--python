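# rfdry

Coupled heat–mass–electromagnetic simulation of jujube (winter date) slice
drying under hot air (HA) and radio-frequency-assisted hot air (HA+RF)
schedules, with the drying-kinetics and transfer-coefficient estimators that
parameterise such models.

## Who this is for

Food-process engineers and researchers studying combined convective/dielectric
drying of plant tissue, who need a scriptable, inspectable alternative to
commercial FEM packages for: simulating stage-wise RF application, estimating
effective moisture diffusivity and transfer coefficients from drying curves,
and calibrating the (rarely measured) electrode voltage against reference
data.

## The model

A cylindrical slice (radius 15 mm, thickness 8 mm, initial moisture 79.6%
wet basis) rests on an impermeable tray between parallel RF electrodes
(27.12 MHz, 110 mm gap) in 60 °C / 2.5 m/s air. Interior transport couples
conduction with Fickian moisture diffusion:

```
ρs·Cp·∂T/∂t = ∇·(k∇T) + Q_rf            Q_rf = 2π·f·ε0·ε″·|E|²
∂C/∂t       = ∇·(D_eff∇C)
```

with evaporative–convective boundary conditions on the exposed faces:

```
k∇T·n      = h_T·(T_air − T_s) − h_fg·h_m·(C_s − C_eq)
−D_eff∇C·n = h_m·(C_s − C_eq)
```

Cp, k, ε′ and ε″ are measured bilinear regressions in temperature and
wet-basis moisture, so the field, the heating and the drying all feed back on
each other. The quasi-static RF field obeys a complex-coefficient Laplace
equation `−∇·((σ + j2πf·ε0·ε*)∇V) = 0`, solved either as a layered series
capacitor (default) or on a 2-D axisymmetric grid. Drying curves are reduced
through the moisture ratio `MR = (M − Me)/(M0 − Me)` and the lag model
`MR = Lf·exp(−S·t)`, from which the mass Biot number
(`Lf = exp(0.2533·Bi/(1.3+Bi))`), the first slab eigenvalue
`μ₁ = atan(0.640443·Bi + 0.380397)`, the effective diffusivity
`D = S·L²/μ₁²` and the mass-transfer coefficient `h_m = Bi·D/L` follow in
closed form. The convective coefficient uses the laminar flat-plate
correlation `Nu = 0.664·Re^0.5·Pr^0.33`.

The discretisation is conservative cell-centred finite volumes with
backward-Euler stepping and Picard lagging of the nonlinear properties
(unconditionally stable at the 1 s default step). See `docs/methods.md` for
assumptions, defaults and limitations.

## Worked example

`examples/run_drying_scenarios.py` simulates all four canonical schedules
(the 4.5 h process split into three 1.5 h stages, RF in none / the early /
middle / late stage):

```
scenario    t @ M=1.0  final M_db  peak T_center  peak T_surf
HA              3.36 h       0.649          54.9C        55.1C
E-HA+RF         2.46 h       0.466          56.4C        56.6C
M-HA+RF         2.66 h       0.466          63.0C        60.0C
L-HA+RF         3.23 h       0.466          70.2C        66.2C
```

Every RF schedule reaches the 1.0 kg/kg dry-basis target before hot air
alone, the centre runs hotter than the surface while RF is on (volumetric
heating), and the later the RF stage the higher the peak — drier tissue has a
smaller loss factor, shields the field less, and so absorbs more power.
The other scripts in `examples/` walk through the property regressions, the
kinetics fit, the field solver and the voltage calibration, one capability
each.

The same runs are available from the shell:

```bash
rfdry simulate --scenario M-HA+RF --out m_harf.csv
rfdry props --quantity loss --temp 60 --moisture 0.796
rfdry fit-kinetics --input curve.csv --half-thickness 0.004
```

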