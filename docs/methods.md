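# Methods

## Scope and model class

`coaxtherm` models a 434 MHz coaxial TEM hyperthermia applicator heating a
cylindrical agar-gel phantom, and the thermometry used to characterize it.
The device is a body of revolution and is fed in the rotationally symmetric
TEM-like mode, so all solvers work on an axisymmetric (r, z) half-plane.
For this symmetry class the reduction is exact in the continuum limit; it
is not a general 3D solver and non-axisymmetric modes are out of scope.

Coordinates: z = 0 at the aperture center (the VOI center), z increasing
upward; lengths are centimeters at the interface and meters internally.

## Geometry conventions

The published device dimensions are d = 3.5 cm (inner-conductor outer
diameter), D = 11.7 cm (outer-conductor inner diameter, from the 50 Ω
constraint Z = 138·log10(D/d)/√ε_r), aperture w = 1.7 cm, outer-conductor
height h = 8 cm, phantom 3 cm diameter × 10 cm. Construction details not
fixed by those numbers are conventions of this package:

- Wall thicknesses: brass walls 1 mm, PVC tube wall 1.5 mm, with the
  inner-conductor shell extending inward from r = d/2. These are the unique
  round values for which the 3 cm phantom plus its tube exactly fill the
  3.5 cm bore, as the device description requires.
- Closures: the outer conductor is closed at the bottom by a plate carrying
  the feed and open at the top; the inner-conductor bore is closed at the
  bottom (where the feed-line core attaches) and open at the top (where the
  phantom tube is inserted).
- Phantom position: the gel column sits 1 cm higher above the aperture than
  below (z from −4 to +6 cm). This keeps every fiber-optic measuring point
  of the probe layout inside the gel (see below); the EM/thermal effect of
  the offset is negligible because the fields decay within ~2 cm of the
  aperture.
- Feed: a delta-gap source — one grid cell of the bottom plate next to the
  inner conductor is driven by a 1 V harmonic source behind a lumped 50 Ω
  resistance. Feed voltage and current are measured at a port plane a few
  cells up the coax. A delta gap in a plate radiates a small fraction
  (~15–20 %) of the source power backward through its slot; this affects
  only the absolute drawn power, not any rescaled thermal result.

## Electromagnetic solver

FDTD on a staggered Yee grid in (r, z) for (E_r, E_z, H_φ): leap-frog
second-order updates, semi-implicit conductivity terms, on-axis E_z update
from the Ampère contour integral, PEC condition enforced by zeroing
tangential E on every edge adjacent to a conductor cell. Open boundaries
use a first-order absorbing (Mur) condition with the local wave speed, so
the top of a uniform coax section behaves as a matched termination — the
basis of the transmission-line validation, which reproduces the closed-form
characteristic impedance to ~0.5 %.

Numerical choices: time step 0.95 of the 2D stability limit of the smallest
cell; source amplitude ramped over 3 periods; the run stops when the
cycle-to-cycle relative change of the feed-current amplitude drops below
1e-4 (default; max 60 periods, non-convergence is flagged, never silent).
Phasors are extracted by projection onto the drive frequency over one full
period; H is phase-corrected for its half-step offset. SAR is the
per-cell point value p/ρ with p = ½σ(|E_r|²+|E_z|²); no mass averaging.

The grid is non-uniform: 0.5 mm (characterization) or 1 mm (sweeps,
default acceptance runs) in the phantom and around the aperture, 2 mm
through the rest of the applicator, geometrically graded to 5–10 mm across
the padding (17.3 cm default, reducible for fast tests). Grid lines snap to
every material boundary and thin layers are subdivided so each is at least
two cells across. Focus SAR per absorbed watt changes < 3 % between 1 mm
and 0.5 mm.

## Thermal solver

Conservative finite-volume discretization of transient conduction in
cylindrical coordinates with harmonic-mean face conductivities, Dirichlet
ambient temperature (21.5 °C default) on the outer boundary, initial state
ambient everywhere. Implicit Euler stepping (default 1 s; accuracy, not
stability, sets the step — halving it changes a 40-min transient by
< 0.05 °C); the operator factorization is cached and reused across runs and
power levels. Against the uniformly heated infinite cylinder with fixed
surface temperature the steady state matches q(R²−r²)/(4k) to < 1 %, and
the per-step energy balance holds to machine precision by construction.

The thin brass walls are excluded from the thermal problem. Default
reading: thermally transparent sheets — conduction passes through them with
the surrounding dielectric's (HDPE) properties. The alternative reading
(highly conducting metal retained, approximating isothermal sheets) is
available via `metal_mode="metal"`; it lowers the 3.6 W peak by ~2 °C.

The EM loss field is computed once per geometry and linearly rescaled so
its volume integral equals the effectively supplied power of each schedule
segment (material properties are temperature-independent). The fraction of
power deposited in the VOI (α) uses the delivered power at the feed port as
its denominator.

## Dosimetry

The VOI is a 1 cm³ cube centered on the axis at the aperture center. It is
not a body of revolution, so VOI statistics sample the axisymmetric field
on a regular 40³ lattice inside the cube (equal-volume samples, bilinear
interpolation in (r, z)); integrating the constant-1 field this way
recovers the cube volume to ≪ 1 %. Percentiles follow the exceedance
convention of hyperthermia dosimetry (T5 exceeded in ≥ 5 % of the volume);
the implementation is verified against a brute-force volume-weighted
sorting oracle. η_T uses temperatures in °C.

## Closed-loop control

`run_controlled` applies proportional–integral feedback on the VOI-center
probe temperature: P = clip(k_p e + (k_p/t_i)∫e, 0, 20 W) with conditional
integration as anti-windup; defaults k_p = 5 W/°C, t_i = 60 s. At a 43 °C
target this reproduces the characteristic maintenance waveform — a clipped
high-power burst (~20 W for about 2 min) followed by a ~2.5–3 W hold — and
holds the center within ±0.5 °C. A scripted waveform
(`maintenance_schedule`: 18 W for 2 min, then a configurable 3–3.4 W hold)
is available when open-loop replay is wanted. Controller instability is
flagged through a configurable overshoot limit.

## Virtual instruments

Pure functions of (solver output, seed); with all noise set to zero they
reproduce the solver values exactly.

- Fiber-optic probes: 14 measuring points on three vertical fibers at
  r = 0, 0.5, 1 cm with 2 cm pitch; #3 at the VOI center, #2/#4 at z = ±2 cm,
  #9 at (0.5, 0), #12 at (1, 0). Fiber insertion depths differ so all
  points lie in the gel; only the five pinned points are constrained by the
  measurement description, the rest of the numbering is a convention.
  A stated "±x °C accuracy" is modelled as Gaussian noise with sd x/2.
- IR camera: the (r, z) half-plane at power-off + delay (default 3 min) is
  mirrored into a full longitudinal section with ±0.2 °C pixel noise. Only
  conduction during the delay is modelled; evaporative/contact cooling of
  the freshly opened split-phantom surface is not.
- Phantom properties: lognormal draws (strictly positive) around the
  measured σ = 0.755 S/m and ε_r = 74 with 2 % relative spread.
- Power meters: 1 Hz samples of the schedule with 1 % multiplicative noise.

## Design study

The sweep covers d ∈ {2.2, 3.5, 4.3} cm × w ∈ {0.7, 1.2, 1.7, 2.2} cm at
h = 8 cm, deriving D per combination from the 50 Ω rule and resizing tube
and phantom to fill each bore. The selection rule is documented and
parameterized: among combinations whose aperture admits standard vials and
whose η_P lies within 10 % of the best value for their diameter, take the
highest α; with the defaults it returns the built design (d = 3.5,
w = 1.7).

Problem sizes used by the shipped experiments: 1 mm fine resolution
(~8 000 cells, a few seconds per EM solve), 40 min + 10 min transients at
1 s steps, 12 min maintenance runs, 5 min + 3 min focus runs.

## Known limitations

- The feed region is an idealized delta gap: the simulated input impedance
  (≈ 4 − 33j Ω, S11 ≈ −1 dB at 434 MHz, flat over 300–600 MHz) does not
  reproduce the matching the physical device achieves through its actual
  connector/transition hardware. Reflection-sensitive quantities should be
  taken qualitatively; nothing downstream depends on them because thermal
  runs rescale the loss field to the effective power.
- The reduced model's longitudinal SAR profile is somewhat broader within
  ±1 cm of the aperture, and weaker at ±2 cm, than the published 3D
  solution appears to be. Consequently simulated 40-min peaks run ~10–20 %
  hot on the temperature-rise scale, the VOI temperature-heterogeneity
  coefficient comes out near 0.034 rather than 0.06, and the longitudinal
  rise decays by ~17 % (not ~50 %) between 0.5 and 1 cm from the center.
  These deviations are stable under grid refinement and construction
  variants and are asserted honestly in the acceptance suite (failing where
  they exceed the published agreement bands).
- No perfusion, thermoregulation, convection or radiation terms: the
  thermal model is pure conduction with temperature-independent properties,
  appropriate for gel phantoms only.
- Synthetic measurements emulate noise amplitudes and acquisition timing,
  not sensor drift, probe self-heating, camera optics or emissivity; tests
  passing on them validate the pipeline, not real-hardware robustness.
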