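# Methods

`fustherm` simulates the temperature and CEM43 thermal-dose fields produced
by focused ultrasound (FUS) in a homogeneous muscle-like block containing
discretely modelled straight blood vessels, and delivers multi-insonation
treatments with fixed or dose-capped power. This note records the model, the
numerics, the parameter choices, and what the synthetic scenarios do and do
not represent.

## Model

Two coupled domains share one temperature field T(x, t):

* **Tissue** (enhanced-conductivity conduction):
  `ρ_t c_pt ∂T/∂t = ∇·(k_eff ∇T) + P_FUS`.
  `k_eff` is an *effective* conductivity that absorbs the convective mixing
  of vessels too small to model individually; there is deliberately no
  Pennes perfusion sink.
* **Vessel lumen** (conduction + axial convection with a parabolic
  Poiseuille profile `w(r) = 2 V_m (1 − r²/R²)`):
  `ρ_b c_pb ∂T/∂t = ∇·(k_b ∇T) − ρ_b c_pb w ∂T/∂z + P_FUS`.

The domains are coupled only through flux continuity at the wall — no wall
heat-transfer coefficient or Nusselt correlation is prescribed; the
conjugate problem resolves the exchange.

**Deposited power.** Acoustics are not modelled. The FUS deposition is a
separable Gaussian `P = P0 Π_u exp(−ln2 · u²/R_u²)` in the beam frame, with
`R_u` equal to *half* the half-power (FWHM) width/height. That reading is a
deliberate choice: the alternative (R_u = full width) makes the focal spot
twice as wide and rescales every absolute temperature; the constructor
exposes `r_trans`/`r_axial` directly so either convention can be used.

**Thermal dose.** CEM43 equivalent minutes,
`TD = ∫ R^(43−T) dt` with R = 0.5 at/above 43 °C and 0.25 below, accumulated
at every solver step (cooling phases included) on the end-of-step
temperature (rectangle rule; the suite documents < 0.5 % quadrature error on
60 s ramps at dt = 0.05 s). Doses are normalized by 240 eq-min, the
conservative muscle-necrosis threshold; normalized dose 1 ⇔ 100 % necrosis.
The solver skips accumulation below 38 °C; the neglected rate is at most
0.25⁵ ≈ 1e-3 eq-min per minute, i.e. < 1e-4 normalized over a full
treatment. `fustherm.dose.accumulate` is exact (no floor) by default.

**Boundary and initial conditions.** Outer tissue faces: Robin exchange
`−k ∂T/∂n = h (T − 37)` with `h = k_eff/d`; `d` stands for the unmodelled
tissue between block and body core and defaults to 20 mm ("a few
centimetres"; a sensitivity switch, since the exact value only matters on
the >100 s boundary-layer timescale). Vessel inlets are held at the 37 °C
core temperature, outlets are pure outflow (zero diffusive flux). T = 37 °C
everywhere at t = 0.

## Material constants (defaults)

| symbol | value | units | meaning |
|---|---|---|---|
| ρ_t, c_pt | 1000, 4000 | kg/m³, J/(kg·K) | tissue density, specific heat |
| k_eff | 1.8 | W/(m·K) | effective tissue conductivity |
| ρ_b, c_pb | 1060, 3840 | kg/m³, J/(kg·K) | blood |
| k_b | 0.6 | W/(m·K) | blood conductivity |
| T_core | 37 | °C | core/arterial temperature |

Tissue diffusivity is then α = 4.5e-7 m²/s, verified against the analytic
heat kernel by the suite.

## Numerics

Finite volumes on a cell-centred grid — Cartesian (x, y transverse, z = beam
axis) or cylindrical (r, z) when the geometry is rotationally symmetric
(single coaxial vessel, on-axis focus). Cylindrical radial faces sit at
r = i·dr, so the r = 0 regularity condition is the vanishing inner face
area.

Each step is operator-split:

1. **Diffusion + source.** Face conductivities are harmonic means (exactly
   flux-continuous across the tissue/lumen wall). Explicit Euler by default
   with the monotone bound `dt ≤ ρc s²/(6k)` enforced (≈59 ms at 0.4 mm
   spacing); a backward-Euler scheme with a cached sparse LU factorization
   is available and is used where a prescribed resolution violates the
   explicit bound. The two schemes cross-validate within 2 %.
2. **Advection.** Backward-Euler first-order upwinding along each axis with
   a nonzero velocity component, solved exactly by substitution in the flow
   direction. This is unconditionally stable and monotone. An *explicit*
   upwind step would demand dt below ~2 ms (Courant ≈ 20–30 at the working
   resolutions), which is why it is not the default despite being the
   simpler scheme; first-order upwinding's numerical axial diffusion mainly
   smears temperature along the lumen, whose content is axially well mixed
   with the cold inlet on sub-second timescales anyway.
3. **Inlet clamp** (lumen cells on the upstream face re-set to 37 °C), then
   **dose accumulation**.

An energy audit (`Simulation.step_audited`) attributes every step's energy
change to source, Robin boundary exchange, advective exchange and the inlet
clamp; the interior-conduction residual is zero to round-off because face
fluxes cancel pairwise.

Rasterization: a cell belongs to a lumen when its centre lies within R of
the axis segment. Radii below one cell are a hard error, below two cells a
warning — the 0.4 mm multi-pair vessels at the 0.4 mm working grid sit at
that warning edge deliberately (the staircase error in lumen volume and
flow is a few percent and grid-converges, as the suite checks).

## Scenarios (the synthetic inputs)

All study inputs are parametric; `make_scenario` builds them:

* `large_artery` / `primary_artery` / `secondary_artery` — single coaxial
  vessels (R/L/Vm = 1.5 mm/200 mm/13 cm/s, 0.5/100/8, 0.3/40/8) in a 60 mm
  transverse block; beam along −z, flow along +z.
* `large_artery_block` — the large artery in a 60×60×40 mm³ block for
  full-3D runs (`angle_deg` tilts the vessel; 90° puts it along x — the
  beam stays on z, which is equivalent to rotating the source and simpler).
* `counterflow_pair` — artery + vein (R = 1.5 mm, Vm = 13 cm/s, antiparallel
  flow) with the block-centre focus 1 mm from each wall.
* `multi_pair` — 21×21×26 mm³ block with 3 pairs of R = 0.5 mm and 6 pairs
  of R = 0.4 mm axial vessels. The artery–vein wall-to-wall gap is
  0.8 mm / 0.6 mm (read as the *surface* separation: centre-to-centre
  0.8 mm would overlap two 0.5 mm lumens). Pair positions are not published
  anywhere we could adopt them from, so the package fixes a uniform,
  versioned layout (`MULTI_PAIR_LAYOUT`): large pairs at x = −6, 0, +6 mm
  on the mid-row, small pairs at the same x on rows y = ±5 mm — uniform
  coverage of the midplane, so every trajectory point has vasculature
  within a few millimetres. Dose statistics are sensitive to this layout;
  it is a constructor argument for sensitivity studies. Pair velocities are
  likewise unpublished; both calibres default to Vm = 8 cm/s (the
  primary/secondary-artery value from the same vessel-size tables).

Transverse extent of the axisymmetric single-vessel runs defaults to a
30 mm radius; the counterflow-pair block is assumed to be the same
60×60×40 mm³ block as the off-axis single-vessel runs.

What the generator does **not** emulate: curved or branching vasculature,
pulsatile or temperature-dependent flow, acoustic propagation (attenuation,
refraction, standing waves), tissue heterogeneity, and perfusion outside the
discrete vessels. Passing tests therefore validate the conjugate
conduction–convection model and the treatment logic, not patient realism.

## Treatments

56 insonations, 20 s on / 5 s cooling, no cooling after the last —
56·20 + 55·5 = 1395 s exactly. Foci live on an 8×7, 2 mm-pitch lattice
centred in the axial midplane (z = 13 mm). Delivery methods: `sequential`
(row-major from top-left), `random` (seeded order with consecutive foci
≥ 8 mm apart, drawn by greedy rejection, ≤10 000 restarts), `spiral`
(outward Archimedean spiral, 2 mm turn spacing and 2 mm arc-length steps
from the block centre). The treatment beam is 3.2/24 mm FWHM; fixed-power
presets are 16.5 W/cm³ (dose studies) and 17.5 W/cm³ (temperature
snapshots) — both printed values are kept because the source text uses
each in a different place.

**Power controller.** The reference study adjusted power *manually* so each
insonation's peak thermal-dose deposition stayed within 230–250 eq-min; the
package's reproducible surrogate trial-simulates each event from a
checkpoint and searches the peak power with a bracketing secant on
(log P0, log dose), warm-started from the previous event's accepted power,
capped at 8 trials (nearest accepted on cap). "Peak dose per insonation" is
the maximum over midplane voxels of the dose accrued during that event's
on+cool interval. Because dose is roughly exponential in the local
temperature rise, the 230–250 band corresponds to a ≈0.5 % power window —
3–5 trials per event are typical.

## Statistics

`dose_stats` reports the peak over the full midplane and the mean/SD over
voxels with normalized dose > 0.3 (excluding the cool lumen interiors);
population SD by default (sample SD is a switch; with thousands of masked
voxels the difference is negligible). `peak_reduction` compares plane-wise
peak *rises* above 37 °C between a with-vessel and a no-vessel run; the
"±1 cm" figure is the mean of the two plane reductions.

## Problem sizes used by the shipped runs

The test suite and `scripts/acceptance.py` run the pair block at
0.5–0.75 mm spacing and the multi-pair block at 0.4 mm (the finest spacing
that resolves the 0.4 mm lumens at one cell per radius), dt = 0.05–0.1 s;
random-trajectory quantities average 2–3 seeds, and the uniformity
comparison uses 12-event prefixes of the full schedule across 5 seeds.
These sizes were chosen so a full validation pass completes on a laptop
CPU; the pair-reduction metric changes by <1 pp between 0.5 mm and 0.3 mm
grids.

## Known limitations and systematic differences

* The implementation reproduces its own stated equations to analytic
  accuracy (heat-kernel, Gaussian-source and closed-form dose checks), but
  two headline figures of the reference study disagree with those equations
  as printed, and this package sides with the equations:
  * The no-vessel 60 s focal rise for the 4/30 mm, 15 W/cm³ source is
    34.3 K in closed form (the solver matches to <0.5 %). Against that
    baseline the counterflow pair removes ~60 % of the plane-peak rise
    (grid-converged), substantially more than the published ~35 %/38 %.
  * The free-tissue 20 s rise for the 3.2/24 mm, 17.5 W/cm³ treatment beam
    is 20.7 K in closed form, above the published "about 16 °C" first
    insonation. CEM43 doses amplify temperature differences exponentially,
    so fixed-power dose statistics (especially the build-up-dominated
    sequential and spiral deliveries) run far above the printed means,
    while *relative* and *controlled* quantities (uniformity gain of
    variable power, total peak dose ≈ 1.5–1.7 normalized, mean accepted
    power ≈ 18 W/cm³) agree well.
  The likeliest sources are the study's unreported finite-element mesh
  (under-resolving a ~1.4 mm focal spot and millimetre lumens smooths both
  peaks and sinks) and its manual power bookkeeping.
* First-order upwinding under-resolves the intravascular thermal boundary
  layer at working resolutions; refining 0.5 → 0.3 mm changes the pair
  metric by <1 pp, but sub-0.1 mm wall layers are not claimed.
* The dose controller assumes dose is monotone in P0 (true here) and one
  power per event (no within-event modulation).
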