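# Methods

## Problem and approach

Thermometric PMI estimation exploits the fact that a body cools towards
ambient temperature after death. Instead of fitting an empirical
weight-classified curve to a rectal temperature, `thermopmi` builds a
mechanistic, individualised forward model: the actual body geometry and
posture (a scaled surface mesh from photogrammetry) is discretised onto
a cubic grid, post-mortem heat exchange with the environment is
simulated forward from death, and each measured skin temperature is
inverted against the simulated cooling curve of its own co-registered
skin location. The package therefore has three computational cores —
voxelization, an explicit finite-difference heat solver, and
look-up-table inversion — plus benchmarking utilities (ring-ROI
thermometry, a standard-method comparator) and a synthetic phantom
generator that stands in for protected cadaver data.

## Voxelization

A cube becomes tissue iff its centre lies inside the closed surface.
The inside test is scanline ray-parity: for every grid column (fixed
y, z) the axis-parallel line is intersected with all triangles once, and
the parity of crossings below each cube centre decides containment.
Rays that graze a triangle edge/vertex (barycentric coordinate within
1e-9 of zero), pass through a degenerate edge-on triangle, or produce an
odd crossing count are recast with a jittered origin (~1e-6·Δx, three
deterministic attempts) and finally fall back to the generalized winding
number (Van Oosterom–Strackee solid-angle sum, inside iff |Ω| > 2π).
Meshes are split into face-connected components and the component
interiors are OR-ed, so unions of overlapping closed primitives (the
phantom bodies) and non-convex postures are handled correctly; each
component must be closed, enforced as a free-edge fraction ≤ 0.02.

Grid convention: 0-based indices, cube centre of (i, j, k) at
`origin + (i+½, j+½, k+½)·Δx`, SI metres, default Δx = 1 cm, and 5 cubes
of air padding around the mesh bounding box so that convective and
radiative boundaries have room. Cubes below the floor plane become
substrate; a floor plane cutting through tissue is rejected as an
inconsistency between mesh and scene.

Two tissue types are modelled. Their spatial arrangement is a uniform
sub-surface adipose shell of configurable thickness (default 2 cm,
strict distance-to-skin < thickness via a Euclidean distance transform);
thickness 0 disables the shell, thickness beyond the body radius makes
the body all-adipose. A uniform shell is the simplest arrangement
consistent with a two-compartment body and is exposed as a parameter
because no validated per-body distribution is available without
tomography.

Markers (coded-target positions on loggers a few millimetres above the
skin) snap to the nearest air-facing tissue cube within 3·Δx, ties going
to the lowest (i, j, k) lexicographically. The 3·Δx radius accommodates
the logger stand-off plus mesh noise while still catching gross
mis-registrations.

## Heat transfer solver

Explicit forward-Euler on the cubic grid, temperatures in °C (kelvin
only inside the radiation term). Per face: conduction with
harmonic-mean interface conductivity (the conservative choice across
material discontinuities); at faces exposed to air, Newtonian convection
plus full T⁴ Stefan–Boltzmann radiation (σ = 5.670374419e-8 W·m⁻²·K⁻⁴,
no linearisation — exact and cheap at the 10–20 K gaps involved). Air
cubes are boundary cubes pinned to the piecewise-linear ambient
schedule rather than simulated fluid; modelling scene airflow is out of
scope. The radiative environment temperature defaults to the air
temperature but can be scheduled separately. Faces on the array
boundary are adiabatic; the padding keeps the body away from them, and
the substrate slab bottom is effectively a no-flux plane.

Materials may also be "pinned solids" (k > 0, temperature held at the
schedule): these realise Dirichlet boundaries and are how the 1-D slab
validation pins its rod ends.

Stability: the scheme sub-steps automatically whenever the configured
step (60 s default) exceeds the Fourier bound Δx²·min(ρc/6k) over the
materials present (126 s for the default tissue at 1 cm; the
concrete-like substrate forces two 30 s sub-steps). A non-finite
temperature aborts the run naming the cube and step; a sub-step count
above 1000 is refused as a configuration error.

Initial condition: body-material cubes at 37 °C, everything else at the
ambient schedule value at t = 0 (defaults 37/20 °C, both configurable).
Conduction is computed once per face and applied antisymmetrically, so
with insulated boundaries Σρc VT is conserved to floating-point
round-off (measured ~1e-16 relative per step over 1000 steps).

Default material table (overridable configuration defaults,
representative literature values): non-adipose tissue k = 0.5 W/m/K,
ρ = 1050 kg/m³, c = 3600 J/kg/K; adipose k = 0.21, ρ = 920, c = 2300;
skin emissivity 0.98; film coefficient h = 5 W/m²/K (still indoor air);
concrete-like substrate k = 1.0, ρ = 2300, c = 880, ε = 0.9.

## PMI inversion

Recording a probe cube every step yields the cooling look-up table.
`reconstruct_pmi` finds the earliest point on the piecewise-linear curve
equal to the measurement (linear interpolation between the 60 s samples;
sub-sample resolution is far finer than the physical accuracy). The
earliest-time tie-break is the conservative choice when the curve is not
strictly monotone. Two flags qualify an estimate: `out_of_range` when
the best residual exceeds the tolerance (default 0.5 °C), and
`near_equilibrium` when the matched segment is flatter than 0.05 °C/h —
near thermal equilibrium a temperature pins the PMI poorly, and the flag
propagates that caveat instead of a spurious point estimate.

Case aggregation references every record to the latest measurement
clock (record k at clock c_k with PMI p_k implies death at c_k − p_k),
takes the median and MAD over ok-status estimates (out-of-range points
carry no time information; if no estimate is `ok`, near-equilibrium
estimates are used rather than refusing the case), and maps
median ± MAD through the clock into a time-of-death interval. Error
analysis utilities report per-site mean ± sd of ΔPMI (reconstructed −
true), the fraction within ±2.8 h (the standard method's best-case
band, kept as the fixed comparison constant), and ΔPMI statistics in
half-open ΔT bins, ΔT being the measured body-ambient difference.

## Thermometry and the standard-method comparator

Ring-ROI extraction averages raster pixels whose centre distance to the
logger centre lies in [r_inner, r_outer) — loggers obscure the skin
beneath them, so the skin reading comes from the ring just outside the
logger border. Pixels outside −40…60 °C are masked; fewer than 10
usable ring pixels is an error. Default ring: logger radius + 1 px,
3 px wide, configurable since no canonical radii exist. The instrument
comparison reports mean ± sd of (camera − logger) — the sign convention
is explicit in the result type — and the Pearson correlation, flagged
undefined on constant series.

The comparator implements the literature-standard double-exponential
Q(t) = A e^{Bt} − (A−1) e^{pBt} with
B = −1.2815(cf·kg)^(−0.625) + 0.0284, A = 1.25, p = 5 for ambient
≤ 23 °C (all validation cases are cool-ambient; the warm branch
A = 1.11, p = 10 sits behind a flag) and solves for t by bracketing root
finding to 1e-4 h — Q is strictly decreasing, so the root is unique.
The constants live in a config dataclass, not hard-coded truths, since
they come from cited literature rather than this package's own
validation. Applicability guards: Q must lie in (0, 1) and a
fever-at-death flag refuses the model, mirroring field practice.

## Synthetic phantoms

The generator emulates the three protected inputs: (i) posed body
meshes as capsule/sphere unions (straight, bent-arm and fetal presets;
default stature 1.70 m, ~6.5×10⁴ tissue cubes at 1 cm — mid-range adult
dimensions), deliberately non-convex with partial substrate contact;
(ii) logger series as forward-simulated probe temperatures plus
independent Gaussian sensor noise (default sd 0.2 °C, a realistic
contact-logger error), sampled by default at 20 times uniform on
2–35 h — the span of true PMIs in the validation studies — under
constant 20 °C ambient over a 36 h simulation; (iii) thermal rasters as
cool logger discs over warmer skin patches with Gaussian pixel noise.
All randomness flows through one seeded generator; a fixed seed gives
byte-identical outputs.

What the phantoms do **not** emulate: real anatomy (bone, cavities —
the mechanism behind the forehead bias seen on real bodies),
heterogeneous clothing and support materials, scene airflow, mesh
reconstruction noise and holes, and model mismatch between the
generating and inverting simulation (inversion here uses the same
forward model that produced the data). Passing recovery tests therefore
demonstrate the *internal* consistency and noise robustness of the
pipeline, not field accuracy on real bodies.

## Validation suite and problem sizes

The acceptance checks pair each core with an independent oracle: exact
interval arithmetic on the two published worked nomogram cases; energy
conservation ≤ 1e-9 relative per step on an enclosed insulated block
(1000 steps); the 1×1×50 slab against the analytic Fourier series
(≤ 0.1 °C at 1/5/10 h; measured ≤ 0.05 °C); sphere voxelization equal
to a brute-force centre-inclusion oracle (exactly) and within 2 % of
4/3πr³; exact look-up round trips; parameter recovery on the capsule
body (5 sites × 20 samples, noise 0.2 °C: |median ΔPMI| ≤ 0.5 h and
MAD ≤ 1.5 h for ΔT ≥ 5 °C, near-equilibrium flag rate > 50 % for
ΔT < 1 °C); and recovery of a −0.27 ± 0.61 °C instrument offset from
155 synthetic pairs within 3 standard errors. These sizes were chosen
as the smallest that exercise every term of the model while keeping the
whole suite around a minute of CPU; the full-body forward run itself
takes ~35 s (Δx = 1 cm, 36 h at 60 s steps with 2 sub-steps).

## Known limitations

- Two-compartment tissue model with a uniform adipose shell; no bones,
  cavities, clothing layers or moisture/evaporation.
- No metabolic/supravital heat production; cooling starts at a uniform
  37 °C body temperature at death.
- Convection uses a single film coefficient per material; no airflow
  modelling or posture-dependent h.
- Point-by-point inversion only; joint curve matching over a whole
  logger series and parameter optimisation over unknown ambient
  conditions are deliberate extensions, not implemented.
- The comparator implements the standard model's published equations;
  practitioner corrective-factor tables are a user-supplied scalar.
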