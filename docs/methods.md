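# Model and methods

## The physical model

Two opposing monolayers of short zwitterionic head-group chains face each
other across a sliding interface, each tethered to a rigid triangular
lattice that stands in for the hydrophobic interior of a surfactant vesicle
pressed flat in a surface-force-apparatus contact.  The bottom lattice
(SUB) is frozen; the top one (SUP) is a rigid body free to translate in
x, y, z.  A stage towed at constant velocity v_stage pulls the SUP layer
through a spring of stiffness k = 1 eV/nm² (≈ 0.16 N/m) along x, while a
normal load L (0–20 MPa over the cell area) presses it down.  The
instantaneous shear stress is k·(x_stage − x_SUP)/A.

Each molecule is a chain of seven beads, CA–R1–R2–R3–AN–NP1–NP2, with
masses 60, 15, 15, 15, 80, 50, 50 a.m.u.  The cation CA carries +q and the
anion AN −q with q = 0.25 e (q = 0 in the charge-free control).  The NP1/NP2
tail pair is planted on one in four nodes of its layer's rigid lattice
(node spacing a/2 = 0.41 nm, molecule spacing a = 0.82 nm, areal density
1.72 nm⁻²).

### Geometry

To avoid artificial perfect commensuration, the two lattices are rotated
by ±φ/2.  A rectangle (l_x, 0) × (0, l_y) tiles a triangular lattice of
spacing a rotated by −χ exactly when (l_x, 0) is the rotated image of an
integer lattice vector v = p·a1 + q·a2 and (0, l_y) of an integer vector
orthogonal to it; the mirror symmetry of the triangular lattice about the
x axis makes the same rectangle tile the +χ lattice, so φ = 2χ.  All
solutions found by the search are exact (zero strain).  The published
system is the minimal rectangle of the (p, q) = (9, 2) coincidence:
φ = 19.653°, 8.322 × 14.414 nm, 206 molecules and 824 rigid beads per
layer (4532 particles).  Desk-scale work uses the minimal in-window cell
with ≥ 30 molecules: the (4, 1) coincidence at φ = 21.787°,
3.758 × 6.509 nm, 42 molecules/layer (924 particles).

The initial pose stacks NP2 and NP1 vertically above the anchor and sends
the AN…CA head segment off at a reduced tilt (default 15° from the layer
normal, azimuth drawn per molecule from a seeded RNG).  Building the full
111° equilibrium kink directly would tilt heads 69° from vertical and
overlap neighbouring beads at the 0.82 nm spacing; the reduced-tilt pose
is overlap-free and relaxes to the equilibrium tilt during running-in.
The SUP lattice is offset by half a node spacing in x so the two anchor
lattices do not start in exact registry, and the two CA planes start
0.5 nm apart (the steady-state separation is set by load and temperature,
not by this choice).

### Force field

* Bonds: E = (k/2)(r − r_eq)², k = 480 N/m (= 2996 eV/nm²; the printed
  value is the literal second derivative), r_eq = 0.16 nm for the five
  head bonds and 0.67 nm for NP1–NP2.
* Angles: E = (k/2)(θ − θ_eq)², θ_eq = 180° everywhere except the
  NP2–NP1–AN kink at 111°.  The angular stiffness is not printed; the
  default k_angle = 3.0 eV/rad² keeps chains semi-rigid at 300 K while
  allowing the out-of-plane excursions that drive interlocking.  It is a
  config parameter, not a model claim.
* Tail-verticality restraint: a harmonic term (k_tilt/2)·θ² per molecule
  in the angle θ between the NP2→NP1 bond and the outward layer normal
  (equivalent to a node–NP2–NP1 angle with θ_eq = 180°), default
  k_tilt = 3.0 eV/rad².  This member of the (incompletely specified)
  angular-interaction set is required for mechanical consistency: without
  it the lateral offset between the NP1 and NP2 nets is a zero-energy
  collective mode — NP1 sits 1.08 nm above the rigid plane, outside the
  1 nm Morse cutoff, so nothing in the pair tables penalizes a collective
  chain tilt — and the bilayer flattens and interdigitates under any of
  the nominal 0–20 MPa loads instead of supporting them.  The default is
  sized like the other angular springs and calibrated only to that
  load-bearing requirement; it leaves the head segment's thermal swing
  (the interlocking mechanism) unconstrained.  Config-exposed.
* Non-bonded pairs: Morse, M(r) = D0[e^(−2α(r−r0)) − 2e^(−α(r−r0))],
  α = 15 nm⁻¹, with shift and linear tail so V(R_c) = V′(R_c) = 0 at
  R_c = 1 nm.  Defaults D0 = 0.010 eV, r0 = 0.41 nm; NP beads bind to
  their own rigid layer with D0 = 5 eV (r0 = 0.41 nm) and to the matching
  NP bead of neighbouring molecules with D0 = 5 eV at r0 = a = 0.82 nm.
  Cross-layer Morse interactions exist only between polar-head beads
  (CA, R1–R3, AN); every rigid–rigid and cross-layer tail/rigid
  combination has D0 = 0.
* Intramolecular exclusions: 1–2, 1–3 and 1–4 pairs take no Morse or
  Coulomb terms (the common MD default resolving the unstated cases);
  the 1–5 CA···AN pair interacts fully.
* Electrostatics: Ewald summation for the xy-periodic slab: an
  erfc-damped real-space sum inside r_cut, a reciprocal-space sum with
  Gaussian self-energy, and the Yeh–Berkowitz dipole correction with the
  box padded in z to ≥ 3× the occupied slab.  The target force accuracy
  is 1e-4 eV/nm.  The α/r_cut/k-space-cutoff split is a solver knob (the
  total is splitting-invariant, which the suite verifies against a direct
  periodic-image sum); defaults are chosen from the accuracy target and
  the box's minimum-image radius.

Pair energies and forces are evaluated from per-interval cubic
(Hermite-constructed) tables on an r² grid, 2048 intervals from
r = 0.02 nm to the cutoff.  The tabulated force is the exact polynomial
derivative of the tabulated energy, so force–energy consistency holds to
machine precision by construction; the tables match the closed forms to
~1e-6 eV (energies) in the dynamically accessible region.

### Dynamics

Velocity-Verlet with a Langevin thermostat acting **only on y and z of the
molecule beads** (friction −mγv_u plus Gaussian noise of variance
2mγk_BT/Δt per step, γ = 1 ps⁻¹), so no thermostat damping biases the
sliding direction.  SUB rigid beads never move; SUP rigid beads translate
as one body under the sum of their members' forces, the load −L·A ẑ and
(in production) the pulling spring.  During running-in the SUP x velocity
is clamped to v_stage instead and no spring is attached; production starts
with the stage at the SUP position (zero elongation).

Timestep: the stiffest mode is a 0.16 nm bond between 15 a.m.u. beads
(period ≈ 32 fs).  The library default Δt = 1 fs (~32 steps/period) is
used for every conservation-sensitive check; the desk-scale sliding
protocol uses Δt = 2 fs (~16 steps/period), stabilised by the thermostat.
Reciprocal-space Coulomb forces vary on ~ps timescales and are refreshed
every `recip_every` steps (20 in desk runs, i.e. every 40 fs) and held in
between; they remain exactly momentum-free while held.  Neighbour lists
are two-level (long candidate list with a 0.8 nm reservoir rebuilt every
200 steps, short lists with a 0.2 nm skin refiltered every 20 steps) on
fixed step schedules, which makes restarted runs bit-identical to
uninterrupted ones given the same chunking; snapshots capture positions,
velocities, cached forces, neighbour lists and the RNG state.

The SUP rigid-body mass uses 50 a.m.u. per rigid bead (not printed; it
only affects inertial transients and is config-exposed).  SUP z motion is
fully dynamic under load — the interlayer distance is an emergent
observable, not a constraint.

### Protocol

Full-scale protocol: running-in (default 10 nm of SUP travel at constant
velocity), then 100 nm of spring-driven production; averages discard a
20 nm initial transient and in stick-slip at least everything before the
first slip event.  Desk-scale protocol (the `desk_plan`): 42
molecules/layer, 2.5 nm running-in, ~4–8 nm production sampled every
0.01 nm of stage travel, discard = 25% of production plus the first-slip
rule — the same shape as the full protocol at reduced travel, sized so the
whole qualitative suite runs on one CPU in tens of minutes.

### Observables

* Hooking fraction h: percentage of molecules (both layers counted) whose
  CA bead crosses the opposing layer's mean CA plane by ≥ δz (δz = 0
  default).  The reference plane species (CA or AN) and margin are
  configurable, since the quantitative definition in the source material
  is not fully specified; the CA plane is the natural choice because the
  interlocking spots are cations reaching through the opposing cation
  plane.
* Interlayer distance: mean z of SUP rigid beads minus mean z of SUB
  rigid beads.
* Regime: stick-slip iff ≥ 2 slip events; a slip is a drop of the
  (0.25 nm moving-average) smoothed stress by ≥ 50% of the running local
  peak within ≤ 1 nm of stage travel, with absolute magnitude ≥ 25% of
  the trace's 5–95 percentile span (rejects thermal ripple on near-zero
  smooth traces); after a slip, detection re-arms only once the stress
  climbs off the trough by 10% of the span (prevents double counting).
* ρ_Uh: Pearson correlation between total potential energy U and h over
  the retained window, computed by a single-pass co-moment recursion
  (verified against the two-pass formula to 1e-12).  Undefined (NaN) when
  var(h) = 0, i.e. in smooth sliding.
* Critical velocity: midpoint between the fastest stick-slip and slowest
  smooth velocity of a sweep, reported with the bracketing pair.
* Transient-bond estimate: ΔE = 2k_C q²(1/r_hook − 1/r_flat) ≈ 86 meV for
  q = 0.25 e, r_hook = 0.41 nm, r_flat = 0.51 nm — the Coulomb gain of a
  cation bridging two opposing anions, comparable to k_BT near 1000 K.

## What the synthetic fixtures do and do not show

`mini_system` builds aligned-lattice (φ = 0) bilayers with the full
template and topology for millisecond-scale tests; boxes smaller than
twice the Morse cutoff are only used for counting/topology checks, because
single-minimum-image forces are discontinuous there.  `synthetic_trace`
fabricates flat/sawtooth/noisy traces with closed-form statistics for the
analysis code.  Passing these tests validates the machinery, not the
tribology; the qualitative physics claims (smooth sliding at low T,
thermally activated stick-slip, charge-free disorder, weak load
dependence) are checked on the desk-scale commensurate system, which
shares the full system's construction but not its size: absolute stress
levels are not comparable to the published full-cell values (the same
spring acts on a ~5× smaller area), so those runs are judged on regime,
ordering and sign, not magnitudes.  No solvent, screening physics,
vesicle elasticity or surface roughness is modelled at any scale.

## Numerical choices and degenerate inputs

* Harmonic convention: printed stiffnesses are second derivatives
  (E = k/2·x²), so 480 N/m converts to 2996 eV/nm².
* Units: eV, nm, ps, e; masses converted once to eV·ps²/nm²
  (1 a.m.u. = 1.03643e-2); 1 eV/nm³ = 160.218 MPa; k_C = 1.439964 eV·nm.
* Angle forces use the (θ − θ_eq)/sin θ form with sin θ floored at 1e-8;
  the ratio is finite at the θ_eq = 180° equilibrium.
* Degenerate bonds (r = 0), coincident angle beads and charged-bead
  overlaps (r < 1e-4 nm) raise immediately; non-finite coordinates abort
  the run with a diagnostic and the partial trace attached.
* Ties in the commensuration search break by |φ − window centre|, then by
  l_x; all reported solutions are exact, so the mismatch tolerance only
  gates future approximate extensions.

## Known limitations

* The reciprocal-space refresh interval (≤ 40 fs) and the 2 fs desk
  timestep trade a little integration accuracy for tractable wall time;
  every conservation test runs at the 1 fs default with per-step Ewald.
* The angular stiffness, the tail restraint, the SUP bead mass, the
  running-in length and the exact hooking-fraction definition are not
  fixed by the source material; all are exposed in configuration with the
  defaults above.
* Desk-scale friction magnitudes are not comparable to full-scale ones.
  With the spring stiffness fixed at k = 1 eV/nm², the 42-molecule cell's
  5× smaller area makes the stage 5× stiffer per unit stress
  (6.55 vs 1.34 MPa per nm of elongation), and under load the
  coarse-grained head carpets partially interdigitate at every
  temperature, adding a large plowing baseline (~25 MPa) on top of which
  the stick-slip physics rides.  The microscopic mechanism is present and
  visible in long desk runs — a 300 K slip drops the stress by ~20 MPa
  within a fraction of a nm while the hooking fraction collapses from
  ~36% to ~1%, and the charge-free system shows shorter-period,
  smaller-amplitude slip cycles — but the stick periods (~2 nm charge-free,
  ~8 nm zwitterionic) exceed what the bundled test runs can traverse, and
  the slip drops (25–45% of the local peak) fall below the 50%-drop
  detection rule adopted for full-scale-like traces.  The qualitative
  regime-contrast checks in the acceptance suite therefore fail at desk
  scale and are retained as failing; a full-size (206-molecule) probe
  loads at the expected 1.6 MPa/nm with single-digit hooking fractions,
  indicating the published stress scale is a property of the full system
  size, not reachable in desk-budget runs.
* Stick-slip statistics at desk scale rest on a handful of slip events
  per run; mean-stress values carry large RMS bars, as reported.
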