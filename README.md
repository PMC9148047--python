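# coaxtherm

An electromagnetic–thermal simulation pipeline for designing and
characterizing a 434 MHz coaxial TEM applicator for in-vitro hyperthermia
experiments: a device that heats a 1 cm³ volume of interest (VOI) inside a
muscle-mimicking agar-gel phantom with a controllable, well-focused
temperature rise.

It is written for medical-physics and RF engineers who want a desk-scale,
fully scriptable counterpart of the usual commercial-solver workflow:
field solution → SAR dosimetry → transient bioheat response → virtual
thermometry, all driven from plain Python or a small CLI.

## The device and the model

The applicator is an open-ended coaxial line: a hollow inner conductor
(outer diameter *d*) carrying a circumferential aperture of width *w*, an
outer conductor (inner diameter *D*), HDPE dielectric between them, and the
phantom in a PVC tube inside the inner-conductor bore. A 50 Ω match fixes
the conductor ratio through the coax impedance relation

    Z = 138 · log10(D/d) / √ε_r,dielectric ,

so *Z* = 50 Ω with *d* = 3.5 cm and HDPE (ε_r = 2.1) gives *D* = 11.7 cm —
the built prototype.

Because the device is a body of revolution driven in the rotationally
symmetric TEM-like mode, the package solves Maxwell's curl equations for
(E_r, E_z, H_φ) on an (r, z) half-plane with an FDTD leap-frog scheme:
staggered Yee grid, perfect-electric-conductor walls, first-order absorbing
outer boundaries, and a lumped 1 V / 50 Ω harmonic source across the feed
gap. Steady-state phasors are extracted by single-frequency projection, and
the loss density p = ½ σ |E|² (SAR = p/ρ) feeds a conservative
finite-volume solution of transient heat conduction

    ρ C_p ∂T/∂t = ∇·(k ∇T) + P_loss ,   T|∂Ω = T_ext ,

with implicit (unconditionally stable) time stepping. Dosimetry follows the
hyperthermia exceedance-percentile convention: P5/T5 are values exceeded in
at least 5 % of the VOI, P95/T95 in at least 95 %, and the heterogeneity
coefficients are η_P = (P5−P95)/P5 and η_T = (T5−T95)/T5. A
proportional–integral power controller reproduces the closed-loop
43 °C-maintenance protocol, and a virtual-instrument layer emulates the
fiber-optic probe array (±0.1 °C), the split-phantom IR camera (±0.2 °C)
and the power meters.

## Worked example

```python
from coaxtherm import *
from coaxtherm.study import prototype_solution

# 50-ohm sizing of the prototype
coax_impedance(11.7, 3.5, 2.1)     # -> 49.911  (ohm)
solve_outer_diameter(50, 3.5, 2.1) # -> 11.725  (cm, rounds to 11.7)

# one EM solve of the prototype at 1 mm resolution, then a 40-min
# heating transient at 3.6 W effective power
proto = prototype_solution(grid=GridSpec(fine_mm=1.0))
loss = scale_loss(proto.loss, 3.6)
series = run_transient(proto.map, loss, PowerSchedule.constant(3.6, 2400),
                       probe_points={3: (0.0, 0.0), 9: (0.5, 0.0), 12: (1.0, 0.0)})
print(round(eta_P(proto.loss), 3))            # 0.152   power heterogeneity in the VOI
print(series.probe_traces[3].max())           # 52.5 C  peak at the VOI center
print(series.probe_traces[12].max())          # 49.1 C  peak 1 cm off-axis
```

The probe ids follow the measurement layout: #3 is the VOI center, #9 the
VOI boundary (r = 0.5 cm), #12 the outermost fiber (r = 1 cm). The same
workflows are available from the shell:

```bash
coaxtherm em --out run/                  # fields, SAR profiles, metrics CSV
coaxtherm sweep --out run/               # the 12-combination (d, w) design sweep
coaxtherm experiment transients --out run/ --seed 1
coaxtherm experiment steady --out run/
coaxtherm experiment focus --out run/
```

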