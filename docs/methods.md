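# Methods

## Problem and scope

Continuous-infusion thermodilution derives absolute coronary blood flow
from the steady temperature of saline infused continuously into a coronary
artery.  The technique is only valid if the infusate mixes completely with
blood within the first few centimetres downstream of the catheter.  This
package quantifies that mixing for two catheter topologies — a monorail
infusion catheter with four ~100 µm side holes and the
pressure/temperature wire inside its lumen, and a conventional
microcatheter with a single end hole and the wire alongside — in an
idealized straight coronary segment (4 mm diameter, 70 mm long, outlets
10 mm in).

Three complementary assessments are implemented:

1. **cross-section mixing statistics** (SD_t and the entropy ratio E) on
   simulated temperature fields;
2. **pullback deviation analysis** of a sensor retracted from 6 cm distal
   back to the catheter tip;
3. a **projectional pass/fail classifier** that operationalizes the visual
   "uniform colour over the diameter within 1–3 cm" judgement used with
   ink injections.

## Study design

Mean coronary flow is LOW/MED/HIGH = 50/150/250 mL/min; infusion rates
span 8–30 mL/min, restricted to the nine clinically used
(category, rate) cells (LOW×{8,10,15}, MED×{15,20,25}, HIGH×{20,25,30});
four cells per catheter are simulated (LOW:8, LOW:15, MED:15, HIGH:25).
Blood is 37 °C.  Two infusate temperatures are carried as presets: 29 °C
for the simulated mode (room-temperature saline warms inside the catheter
in the body) and 23 °C for the bench mode (room-temperature saline
injected directly).  The pullback analysis uses the bench mode; the field
statistics use the simulated mode.

The perfect-mixing dilution fraction is `P* = Qi / (Qb + Qi)` and the
perfect-mixing (mixed-cup) temperature `Tmix = Tb − P*(Tb − Ti)`.

## Transport model

The simulator is a deliberately reduced stand-in for 3D CFD.  Its contract
is (a) exact scalar conservation and boundedness, and (b) the qualitative
injection-topology contrast — rapid homogenization for distributed wall
jets versus a persistent axial cold core — not pointwise solver fidelity.

* **Grid**: structured cylindrical-section cells (axial × radial ×
  angular).  Default analysis resolution 42×8×12 (≈1.7 mm × 0.25 mm ×
  30°); `SolverResolution()` gives 63×10×16.  Catheter and wire cells are
  masked solid; the wire runs on the axis (side-hole) or offset beside the
  catheter (end-hole), making that geometry non-axisymmetric.
* **Velocity**: quasi-steady laminar profile per cross-section, obtained
  by solving a unit-forced Poisson problem on the open cells (no-slip at
  vessel wall, catheter and wire), rescaled each time step so every plane
  carries the instantaneous coronary flow plus, downstream of the outlets,
  the injected flow.  In-plane redistribution fluxes, computed from a
  per-plane graph-Laplacian potential, cancel the axial continuity excess
  cell by cell, so the discrete flux field is exactly divergence-free with
  the injection appearing as volumetric sources.  There is no momentum
  solve, turbulence model, vessel curvature or compression.
* **Waveform**: diastolic-dominant two half-sine lobes (systolic fraction
  0.35, systolic dip = pulsatility, default 0.9), unit mean in closed
  form, non-negative.  The shape is a generic coronary-like choice; the
  mixing statistics are insensitive to it at the cycle-averaged level.
* **Injection**: side-hole — four wall jets at 90° spacing; each jet exit
  velocity is O(10 m/s) against an O(0.1 m/s) crossflow, so the jets
  traverse the lumen and the source is deposited along each jet's radial
  column *in proportion to the local axial flux* (each streamtube receives
  the same dilution), with a small ±1-sector angular fan.  End-hole — one
  axial source over the open catheter-mouth cells.  Total source equals
  the infusion rate exactly.
* **Scalar step**: explicit donor-cell upwind advection on all faces
  (CFL-limited fixed step, typically 1–5 ms) followed by implicit
  (backward-Euler) transverse diffusion per plane, factorized once per
  (mask pattern, diffusivity level).  Both sub-steps are conservative and
  monotone, so lumen temperatures stay within [Ti, Tb] and the
  cycle-averaged flow-weighted temperature at any downstream section
  equals Tmix at periodic steady state (measured ≤0.2% of the Tb−Tmix
  contrast).
* **Effective diffusivity** (the calibration knob): D(z) = α_water +
  C·u_jet·d_jet·exp(−(z−z0)/L) with α_water = 0.143 mm²/s, L = 15 mm,
  C_side = 0.02 and C_end = 0.002.  The jet-scale term stands in for the
  turbulent/secondary-flow mixing the reduced solver cannot resolve.
  C_side is set so side-hole injection is near-homogeneous (E ≥ 0.95) by
  1.2 cm; C_end is an order of magnitude smaller because the coaxial
  end-hole jet shears rather than crosses the flow, which preserves the
  cold core over several centimetres.
* **Cycles and initial state**: uniform blood temperature at t = 0; the
  first cycle is discarded and statistics use the final cycle.  Two 1 s
  cycles suffice at MED/HIGH flow; at LOW flow (50 mL/min) the washout
  transit alone is ≈0.9 s, so steady-state checks run three cycles.

## Mixing statistics

Sample points form a deterministic polar lattice of 8 equal-area rings ×
16 angles (128 points, each representing the same lumen area).  Points
whose area patch touches the wire footprint are excluded.  Per point the
temperature is time-averaged over the final cycle (periodic-trapezoid
weights over the stored snapshots; bilinear in-plane interpolation).

* `SD_t` — RMS deviation of the time-averaged temperatures over unmasked
  points (0 ⇔ uniform).  A mean-absolute-deviation variant is available
  (`method="mad"`); both renderings are defensible and the choice is
  documented rather than hidden.
* Dilution probability `P = (Tb − T)/(Tb − Ti)` ∈ [0, 1] (1 = pure
  infusate), clamped with a logged warning on numerical overshoot.
* Entropy ratio `E = mean_k(−P_k ln P_k) / (−P* ln P*)`, with 0·ln 0 := 0.
  The normalization by the perfect-mixing point entropy makes E = 1 at
  homogeneity for any P*; values slightly above 1 are possible because the
  point entropy −P ln P peaks at P = 1/e, not at P*.  When no infusate has
  reached any sample point (all P_k = 0) the numerator vanishes and E is
  reported not calculable.  The ratio is independent of the logarithm
  base; the un-normalized mean entropy is exposed for audit.

Longitudinal profiles evaluate both measures from the injection site to
4.8 cm distal and report the first station where SD_t falls below 0.1 °C.

## Pullback analysis

The clinical recipe, in a fixed order enforced by the types: 2 s centred
rolling mean on the raw trace (shrinking window at the edges), linear
resampling to N = 1000 uniformly spaced positions over the recorded span,
per-point relative deviation from the pullback-mean temperature (computed
on the °C reading as recorded — the percentages are defined on the
measured scale, and this choice changes magnitudes), and the percentage
of points deviating more than 15% and 20%.  The deviation profile has
exactly zero mean by construction, and exceedance is non-increasing in
the threshold.  Recorded traces are ingested from CSV (`time_s`,
`temperature_C`, optional `position_cm`; constant pullback speed over
6 cm assumed when position is absent); a plausibility window of 10–60 s
guards the duration (the protocol uses 15–30 s).

Virtual pullbacks sample the simulated field along a sensor retracting at
constant speed while the field repeats its final cycle periodically.  The
default sensor paths follow the wire that carries the sensor: side-hole —
constant offset just outside the central wire; end-hole — from the jet
axis at the tip drifting linearly to 0.7 R distally, because a manually
pulled floppy wire does not track the jet axis over 6 cm (distally the
sensor reads near-blood temperature, near the tip it is dragged through
the cold core).  Optional Gaussian sensor noise takes an explicit seed;
everything else is deterministic.

## Projectional classifier

The cycle-averaged dilution-probability field is averaged along one
viewing axis (volume-weighted over lumen cells per transverse bin),
mimicking a single-camera view of an ink cloud.  A station passes when
the coefficient of variation of intensity across the projected diameter
is at most `cv_threshold`; the verdict is PASS iff every station within
1–3 cm of the tip passes.  The default threshold 0.35 is an explicit
operationalization of a judgement that was visual and binary in the
laboratory: simulated side-hole projections at MED/15 score CV < 0.01 and
the end-hole cold-core streak scores CV > 1, so the verdict is insensitive
to the exact value over more than two orders of magnitude.  Raising the
threshold can only convert FAIL to PASS.  Pass rates over replicate
verdicts are tabulated stratified by flow category, with exact fractions
and integer-rounded percentages.

## What the synthetic data does and does not show

The generator reproduces the *structure* the analysis assumes: a
conserved bounded scalar, pulsatile through-flow, distributed versus
point injection, wire obstructions and the resulting topology contrast.
It does not model the momentum of the jets beyond their deposition
pattern, buoyancy of the cold saline, non-Newtonian blood rheology,
viscosity/thermal-property contrast between saline and blood, vessel
curvature, cardiac compression or probe motion artifacts.  Passing tests
therefore demonstrate that the *pipeline* (statistics, pullback
processing, classification) behaves correctly on fields with the right
structure, and that the injection-topology contrast is robust under the
model's assumptions — not that the solver reproduces any particular CFD
field pointwise.  Accordingly, reference cross-section values are treated
as ordering/threshold properties (side-hole SD_t near 0 and E near 1 by
1.2 cm; end-hole SD_t orders of magnitude larger and E well below 1),
never as digit-level targets.

## Numerical choices and degenerate inputs

CFL number 0.7 against the worst-case cell filling rate over the cycle
(flux extremes occur at waveform extremes since all fluxes are affine in
the instantaneous flow); diffusivities quantized to 0.25-log-spaced
levels so planes share LU factorizations; temperatures clipped to
[Ti, Tb] after the implicit step to remove ~1e-12 solver round-off;
geometries whose catheter fills the lumen, stations outside the stored
extent, fewer than two unmasked sample points, inverted thermal contrast
(Tb ≤ Ti), zero-mean traces and empty verdict tables all raise typed
errors.  Zero infusion is admitted as an explicit control (field stays at
Tb everywhere).

## Problem sizes

Analysis runs use the 42×8×12 grid with 24 snapshots per cycle (the
refinement smoke test doubles all three axes and moves prox-station SD_t
by <15%).  The full test suite runs in ≈40 s and the acceptance script in
≈20 s on one CPU.
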