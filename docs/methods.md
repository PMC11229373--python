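# Methods

`cgdna` implements a sequence-dependent, one-bead-per-nucleotide
coarse-grained model of duplex B-DNA together with the machinery needed to
parameterise it, simulate it, decode it back to heavy-atom coordinates, and
analyse the resulting ensembles.  This note records the model, the default
parameters and why they were chosen, the synthetic reference data that
stands in for atomistic MD, and the numerical decisions a maintainer would
want to know about.

## The model

Each nucleotide is one bead anchored at the sugar C1' atom, carrying the
nucleotide mass (A 331.2, C 307.2, G 347.2, T 322.2 Da) and one unit
negative charge.  The energy is

    E = E_seq + E_remote,        E_seq = E_seq-4mer + E_seq-distant,

with all bonded terms truncated quartic polynomials

    E(x) = K2 (x − x0)² + K3 (x − x0)³ + K4 (x − x0)⁴ ,

in kcal/mol with distances in Å and angles in radians.  The quadratic term
sets the basal harmonicity, the cubic skews it, and the quartic (kept
strictly ≥ 0) confines large excursions, which is what keeps 0.1-ps
integration stable at high temperature.  Base opening, kinking and melting
are outside the model's regime by construction.

The sequential terms live on 11-bead windows: per bead, stacking with its
two strand neighbours, a backbone angle on each bead triplet, pairing with
its Watson–Crick partner, and "fan" terms with the partner's neighbours up
to ±5 bp.  Local terms are parameterised per tetramer (four consecutive bp
read 5'→3' on the Watson strand, reduced by reverse-complement symmetry to
the lexicographically smaller representative, with Watson/Crick and
first/second-slot roles remapped on the flip).  An interaction shared by
two tetramer windows takes the arithmetic mean of the two parameter sets;
terminal windows that run off a linear end fall back to the
sequence-averaged parameter set.

Two accounting schemes decide which fan offsets are tetramer-specific.
The default `eq5` scheme keeps ±1, ±2 at the tetramer level — giving the
canonical per-window count of 2 stacking + 2 pairing + 4 angle + 8 fan —
and treats ±3, ±4, ±5 as sequence-averaged "distant" terms.  The
alternative `fig1` scheme (selectable everywhere a scheme id is accepted)
keeps ±1..±3 tetramer-specific with ±4, ±5 distant.  The two readings
exist because a per-tetramer assignment of all ±1..±3 offsets is
arithmetically incompatible with an 8-fan-per-window count; the package
implements both rather than guessing.

Remote terms act between all bead pairs more than 5 bp apart along either
strand (closer pairs are already restrained by the bonded window):
a 12-6 Lennard-Jones term with σ = 10 Å, ε = 0.59 kcal/mol, and a
Debye–Hückel screened Coulomb term

    E_ele = C q² exp(−κ r) / (ε_r r),   C = 332.0637 kcal·Å/(mol·e²),

with q = −1 e per bead, ε_r = 78.5 and κ = 0.104 Å⁻¹ (the Debye constant
of 100 mM monovalent salt in water at 300 K).  The cutoff is 2.5 σ = 25 Å
with no switching function; energies are validated against O(N²) pair-loop
oracles, and a k-d-tree pair search (exact, not approximate) takes over
beyond 400 beads.

## Dynamics

Langevin dynamics is integrated with the BAOAB splitting of velocity
Verlet at dt = 0.1 ps by default: half-kick, half-drift, exact
Ornstein–Uhlenbeck velocity update with fluctuation–dissipation noise
amplitude, half-drift, half-kick.  BAOAB was chosen for the accuracy of
its configurational averages at this timestep.  Gaussian deviates come
from a Box–Muller transformation of a seeded PCG64 uniform stream, making
every run bit-reproducible from (inputs, settings, seed).  The friction
default is 1.0 ps⁻¹ (configurable; results are insensitive to moderate
changes).  Forces convert to accelerations through 1 kcal/mol =
418.4 Da·Å²/ps²; k_B = 1.987204×10⁻³ kcal/mol/K.

Two integrator facts worth knowing:

* The *kinetic* temperature carries the usual O((ωdt)²) discretisation
  bias for stiff modes.  With fitted angle stiffnesses (K2 ≈ 40–70
  kcal/mol/rad²) this is a few percent at dt = 0.1 ps and vanishes at
  smaller dt; *configurational* averages are dt-robust (the 18-mer
  end-to-end distance agrees to < 0.1 Å between dt = 0.1, 0.05 and
  0.02 ps).  Thermostat-consistency tests therefore run at dt = 0.02 ps;
  the statistical oracle (harmonic-dimer positional variance) is checked
  at the production dt = 0.1 ps.
* With the quartic confinement active, trajectories remain finite at
  least up to 600 K at dt = 0.1 ps in the stability scan.

## Synthetic reference data

The fitting and back-mapping stages are exercised against synthetic
ensembles that emulate what atomistic MD provides: fluctuating C1'
ensembles and matched heavy-atom frames.  The generator builds base-pair
frames along a contour and is controlled by:

* helix geometry — rise 3.38 Å/bp, twist 34.3°/bp, C1' radius 9 Å,
  inter-strand phase 180° (so every bp midpoint lies exactly on the local
  helix axis; per-dinucleotide-step overrides available);
* `sd_stacking`, `sd_pairing` (defaults 0.3 Å) — target SDs of the
  intra-strand and cross-strand C1'–C1' distances, matching typical
  atomistic B-DNA values.  The per-step rise is solved exactly against
  the sampled chord so the realised stacking SD converges to the target;
* `sd_twist` (default 1.0°) — per-step twist jitter, the dial behind the
  backbone-angle fluctuations.  The default produces a backbone-angle SD
  of ≈ 4° and remote-window (±3..±5 bp) distance SDs of 0.8–1.7 Å, both
  in the range seen in atomistic B-DNA ensembles;
* `persistence_length` (default 60 nm, the scale of atomistic B-DNA
  estimates) — worm-like-chain bending.  Bending is generated as a smooth
  mode: tilt increments are correlated over 16 steps (counter-rotated by
  the accumulated twist so the helical rotation does not cancel the
  mode), which reaches the same tangent-decorrelation rate q = rise/PL
  with a √16-fold smaller per-step bp-plane tilt.  The residual
  contribution of the rigid-bp tilt to the stacking distance is
  subtracted from the requested stacking SD.

Frames are independent draws (no time correlation).  The model is Gaussian
and deliberately omits anharmonicity, sequence-specific fine structure and
slow collective modes of real MD, so tests passing on it demonstrate the
*machinery* (extraction, fitting, decoding, estimation), not force-field
accuracy on real DNA.

Matched heavy-atom frames place idealised nucleotide templates rigidly on
the same bp frames.  The templates are geometric fixtures: planar regular
rings with uniform 1.55 Å bonds, a tilted sugar pentagon and an extended
phosphate arm, with the C1' exactly at the bead anchor and correct heavy
atom counts (A/C/G/T = 21/19/22/20 with 5' phosphate).  They make no
claim of chemical accuracy.

Minicircles are built as planar rings (circumference n·rise) with an
explicit twist registration of (Lk0 + ΔLk)·360°/n per step,
Lk0 = round(n/10.5); ΔLk changes the strand registration around an
identical centreline.

## Fitting

1. **Extraction** — per-instance means and variances of every bonded
   observable, pooled per (tetramer class, role) with one unit weight per
   instance-context; distant offsets pool separately; truncated terminal
   contexts pool into the fallback set.  Covariances between distance
   instances sharing a bead are computed on demand but do not enter the
   default objective.
2. **Baseline** — equilibrium values at the pooled means; K2 from the
   harmonic inversion K2 = k_B T/(2 Var), capped at 100 kcal/mol/Åᵃ;
   K3 = 0; K4 seeded at 1% of K2.
3. **Tetramer refinement** — Because context-averaging makes every
   instance's effective (K2, x0) *linear* in the per-group parameters, a
   global ridge-regularised least-squares solve first lands the
   parameters next to the fixed point.  COBYLA sweeps then polish each
   (class, role) pair in the context of all other current values,
   minimising the summed squared relative errors of the group's implied
   mean and variance, with box constraints (K2 ∈ (0, 100], K4 ≥ 0) and a
   small Tikhonov pull (weight 10⁻³) toward the preconditioned values
   that pins the gauge directions left open by parameter sharing.
   Model-implied observables use the harmonic closed form by default; the
   slower simulation-backed mode re-simulates the current library once per
   sweep and corrects the harmonic surrogate by per-group
   simulated/harmonic bias factors (clamped against short-run noise), so
   anharmonic and coupling effects enter the targets without a simulation
   inside every optimiser step.  Sweeps stop when the max relative
   parameter change drops below 10⁻²; on well-converged references
   (≳ 200 frames) this takes 2–3 sweeps.  Noisy references (tens of
   frames) may not reach the tolerance — the statistics, not the
   optimiser, are the limit there.
   Parameter sharing leaves a per-role gauge freedom (shifting stiffness
   between the two slots that average into the same instance); the
   identifiable quantity, used in recovery checks, is the class-level
   effective stiffness — the mean effective K2 of the instances carrying
   the class context.
4. **Distant refinement** — Metropolis annealing of the distant-term
   (K2, x0) vector over an effective-temperature ladder (up then down),
   with the merit the summed squared relative errors of the simulated
   end-to-end mean and variance of a 40-mer versus targets; the best
   candidate can be polished by conjugate-gradient descent on the same
   merit.  Merit simulations use a fixed seed so the merit is
   deterministic within a run.  Note the end-to-end variance estimated
   from short runs is noisy; robustness comparisons across annealing
   seeds should target the mean (or use long merit simulations).

## Back-mapping

Two linear-decoder stages in the GLIMPS lineage:

* **Backbone stage** (sequence-neutral): every sliding 10-bp window's 20
  beads, superposed by Kabsch onto a canonical ideal-helix window frame,
  predict the 220 backbone heavy atoms of the window through one shared
  ordinary-least-squares map (optional PCA rank reduction).  Overlapping
  window predictions are blended by uniform averaging in the global
  frame; the pre-blend inter-window disagreement is reported as a seam
  RMS diagnostic.  Circular inputs use wrap-around windows.
* **Base stage** (bp-class dependent): the 22 backbone atoms of a bp,
  superposed onto a canonical purine-first bp frame, predict its 19 base
  atoms; A·T/T·A share one map and G·C/C·G the other, pyrimidine-first
  pairs being swapped into the canonical orientation.

Working in superposed local frames makes reconstruction equivariant under
rigid motion to < 10⁻³ Å.  A final soft-sphere steepest descent
(quadratic repulsion below 1.7 Å, per-iteration displacement cap 0.05 Å,
1-2 bonded pairs excluded via the template connectivity) removes residual
clashes; it is a geometric clean-up, explicitly not an atomistic
force-field minimisation, and is flagged as such in output provenance.

## Analysis

All estimators operate on the bp C1'-midpoint curve (recorded in output
metadata; with the default 180° phase this is the exact helical axis) and
are rigid-motion invariant:

* RMSd via Kabsch superposition restricted to proper rotations, with the
  average structure iterated to self-consistency;
* essential modes from the covariance eigendecomposition of superposed
  frames; RMSIP = sqrt((1/n) Σᵢⱼ (vᵢ·wⱼ)²);
* end-to-end distance between the terminal bp midpoints;
* persistence length from a log-linear fit of the tangent correlation
  down to ⟨cos θ⟩ = 0.5, with the contour step measured (not assumed) and
  a +∞ sentinel for non-decaying chains;
* gyration radius and the aspect ratio sqrt(λ_max/λ_min) of the gyration
  tensor;
* chord bending profiles: the angle at each midpoint between the chords
  to the midpoints ±window/2 away.  For a planar n-ring with window w the
  analytic value is w·180°/n (each chord spans w/2 steps; the direction
  change between the two chords is half the enclosed arc);
* writhe by the exact per-segment-pair solid-angle sum (Gauss double
  integral) over closed polygons;
* cross-RMSd matrices with block bookkeeping between ensembles.

## Problem sizes used in the shipped checks

Synthetic references use 400 frames (fitting) and 60 frames (back-map
training); statistical engine checks run 10⁵–10⁶ steps of 2–36 beads; the
end-to-end reproduction simulates 10⁶ steps of the 18-mer and averages
its second half; the stability scan runs 10⁵ steps at each of 300–600 K.
These sizes give sampling errors comfortably inside the stated
tolerances.

## Known limitations

* The Gaussian surrogate cannot teach the fit anything about real
  sequence-dependent anharmonicity; fitted libraries are only as good as
  their reference.
* With only local bonded terms fitted to marginal variances, the model's
  global stiffness is an emergent property; the distant-term refinement
  stage exists precisely to adjust it against long-duplex end-to-end
  targets.
* Kinetic-temperature readings at dt = 0.1 ps are biased low by a few
  percent for stiff fitted libraries (configurational observables are
  unaffected); reduce dt when kinetic diagnostics matter.
* The nucleotide templates are fixtures; decoded structures are suitable
  as starting points or for shape analysis, not as chemically accurate
  models.
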