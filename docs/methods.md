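# Methods

## Scientific setting

The package studies the open↔closed conformational equilibrium of a
hinged protein domain — the prototype being the Josephin domain (JD) of
Ataxin-3, a 171–182-residue globule whose α-helical hairpin (residues
31–62) swings between an "open" arrangement, extended into solvent, and a
"closed" one packed against the globular core.  The analysis chain is the
one practitioners use for such problems: unbiased sampling → essential
dynamics (PCA) to extract the dominant collective motion → well-tempered
metadynamics biasing the first essential coordinate → reweighted-histogram
free-energy surfaces over physically interpretable descriptors (radius of
gyration over residues 1–171 and the three-group hairpin angle).

All-atom explicit-solvent trajectories at the hundreds-of-nanoseconds
scale are not reproducible on a desk, so every stage here runs against a
**synthetic hinged-domain generator with planted ground truth**: the free
energy along the hinge coordinate is known exactly, and the published
landscape values are planted as generator parameters.  Passing the test
suite therefore demonstrates that the *machinery* — propagator, PCA, bias
deposition, reweighting, minima detection — is correct, not that any
all-atom force field would produce these numbers.

## The synthetic hinged domain

A 171-bead Cα-level model with uniform bead masses:

- **Core** (residues 1–30 and 63–171): a Fibonacci-sphere spiral of radius
  `core_radius`, rigid in every frame.
- **Hinge group** (residues 31–35): beads on the rotation axis through the
  hinge point (a short stalk below the core's south pole), with the 32–35
  center of mass exactly at the hinge point.
- **Arm** (residues 36–62): rotates rigidly about the hinge axis.
  Residues 39–62 form a collinear out-and-back hairpin-tip cluster at
  distance `arm_length` along the arm direction; residues 36–38 are
  "strut" beads at a fixed phase offset in the rotation plane, so the
  closed arm packs against the core surface near residues 140–160 (giving
  the closed state its characteristic arm–core contacts).

By construction the three-group hairpin-angle descriptor of a jitter-free
frame **equals the dynamical hinge coordinate θ exactly**: the vertex (the
hinge-group COM) sits on the rotation axis, and the loop-group COM lies on
the arm direction, which makes angle θ with the hinge→globular-group
vector by definition.  Isotropic Gaussian jitter (default σ = 0.05 nm per
bead) stresses every downstream estimator without destroying the state
structure (it adds ≈1° of angle noise and ≈0.003 nm of RG noise).

θ diffuses on a planted quartic double well U(θ) with stationary points at
θ_closed, θ_barrier, θ_open.  Given both well depths (measured from the
barrier top), the barrier position is fixed by the depth ratio and solved
by root finding; the quartic scale then matches the absolute depths.  The
dynamics are overdamped Langevin (Euler–Maruyama),

    θ_{k+1} = θ_k − (dt/γ) U′(θ_k) + sqrt(2 kB T dt/γ) ξ_k,

with γ an angular drag in kJ/mol·ps/rad² (default 100), dt = 0.01 ps and
kB = 0.0083144621 kJ/mol/K.  At the planted curvatures (≈1650 kJ/mol/rad²
in the closed well) this gives a stable, weakly-discretized sampler whose
θ-histogram matches the Boltzmann oracle with KL < 0.003.  Because the
only dynamical variable is θ, the marginal free energy along θ is exactly
U(θ), and along any monotone descriptor of θ it is known by change of
variables — the analytic acceptance surface for the whole pipeline.

**Preset (study conditions).**  θ_closed = 63°, θ_open = 100°, depths
36 and 4 kJ/mol, T = 310 K; geometry calibrated by 2-parameter root
finding on (core_radius, arm_length) so the jitter-free closed/open frames
have RG = 1.55 / 1.78 nm over residues 1–171 (a published landscape
prints the second well as 4 kJ/mol on the RG projection and 5 kJ/mol on
the angle projection; the generator plants 4 and treats the gap as
projection/smoothing noise).  The straight-rod arm of a first design
could not reach the required 0.23 nm RG contrast at these absolute RG
values — beads near the hinge add extension but almost no open/closed
contrast — which motivated the tip-cluster arm profile.

## Essential dynamics

Frames are iteratively Kabsch-superposed to their running mean until the
mean moves < 1e-6 nm RMS; the 3N×3N Cartesian covariance (no mass
weighting) is diagonalized; eigenvector signs are fixed by the
largest-component-positive rule.  Two deliberate choices:

- **Rigid-core fit.**  The pipeline computes the superposition on the
  core residues only (covariance still spans all residues).  A
  whole-molecule fit lets the long arm dominate the rotational moment and
  absorbs about two thirds of the swing into the fitted rotation, which
  suppresses the mode-1-filtered RMSF.  Fitting on the stable subdomain
  is the standard remedy when analysing hinge motion.
- **Alignment reference = converged mean**, not frame 0, removing
  reference bias.

`filter_trajectory` expects pre-aligned input and replaces each frame by
mean + s₁·v₁; projections are then plain inner products and filtering is
exactly idempotent.

## Well-tempered metadynamics

Gaussians of width σ = 0.1 (in the CV's own units; nm for PCA
projections) are deposited every `pace` = 1 ps with initial height
w0 = rate × pace = 0.2 kJ/mol (rate 0.2 kJ/mol·ps) and the well-tempered
damping w = w0·exp(−V(s)/kB ΔT), ΔT = (γ−1)T with bias factor γ = 20.
The bias is the exact hill sum; the integrator reads it through a dense
grid cache (2048 nodes) whose node values are exact running sums — the
linear interpolation between nodes is bounded below 0.02 kJ/mol at the
default resolution, far under kB T ≈ 2.6 kJ/mol.  The bias force enters
the θ-dynamics through the chain rule; for the PCA-projection CV of the
rigid-arm surrogate the projection reduces to the closed form
s(θ) = c0 + c1 cos θ + c2 sin θ (frames are projected without
re-alignment: the core is rigid, so the fit is essentially the identity,
and any smooth monotone reparameterization is an equally valid biasing
coordinate).  With deposition rate 0 the engine is bit-identical to the
unbiased propagator for the same seed.

The well-tempered FES estimate is F(s) = −γ/(γ−1)·V(s, final) + C with C
chosen so min F = 0.

## Reweighted-histogram free energy

Biased frames are reweighted with w_i ∝ exp(+V(s_i)/kB T).  Two schemes
are implemented:

- **final** (default): V = the final bias.  Robust to the early
  exploration transient of runs started in the shallow open well.
- **running**: V(s_i, t_i) truncated at the frame's time, with the
  well-tempered offset c(t) = kBT·ln(∫e^{γ/(γ−1)·V/kBT}/∫e^{V/((γ−1)kBT)})
  maintained incrementally on a grid.  On benchmark runs started in the
  deep well it is ~3× more accurate than the final-bias scheme (max
  deviation 0.23–0.36 vs 0.46–0.98 kJ/mol against the analytic FES), but
  it assumes quasi-equilibrium and mis-weights pre-equilibrium frames
  unless a burn-in is discarded, so the pipeline keeps the final-bias
  default.  Both schemes agree within 1 kJ/mol on benchmarks (tested).

F over the auxiliary descriptors is −kB T·ln of the weighted histogram
(default 100 bins per axis over the sampled range padded 2%; 100×100 for
2D maps), shifted so the sampled minimum is zero; never-sampled bins are
masked.

**Minima and depths.**  Minima are detected on a Gaussian-smoothed grid
(1-bin bandwidth) by topographic persistence: cells are processed in
ascending free energy with union-find merging, and a minimum's **depth**
is the lowest saddle separating it from any deeper minimum, minus its own
value (for the global minimum, the saddle at which the last competitor
merges).  This makes the deep/shallow pair of the planted landscape read
as 36/4 kJ/mol; each minimum's value above the global minimum is reported
alongside.  Minima shallower than `min_depth` (2 kJ/mol) or more than
`fes_max_value` (50 kJ/mol) above the global minimum are suppressed — the
latter removes spurious dips in sampling-starved tail regions.

**Convergence.**  ΔF between two CV basins is recomputed from the bias
truncated at a series of checkpoints; convergence is declared when the
last three checkpoints vary by < 1 kJ/mol.  A single finite run's ΔF(t)
oscillates by ~±1.5 kJ/mol at the desk-scale run length, so the flag is a
diagnostic; seed-averaged final estimates land within ±1 kJ/mol of the
analytic value on benchmarks.

## Desk-scale protocol (problem sizes)

Chosen once from measured relaxation scales of the surrogate and frozen:

- **Unbiased pre-run**: 6 replicas × 2500 steps (25 ps), stride 5,
  started open.  The escape time from the 4 kJ/mol open well is ~2–18 ps,
  so 25 ps replicas dwell in the open state for a meaningful fraction of
  the run before relaxing into the closed well — both basins (and the
  transition) are represented in the PCA ensemble.
- **Metadynamics**: 2×10⁶ steps (20 ns), pace 1 ps → 20 000 hills, CV
  log/frames at stride 40 (50 000 frames).  The closed well (36 kJ/mol)
  fills within the first few ns; the remainder repeatedly recrosses.
- **Acceptance / tests**: landscape-recovery quantities are averaged over
  3 seeds; engine benchmarks use the 15/3 kJ/mol quartic double well at
  310 K (dt = 0.002 ps, γ = 10 kJ/mol·ps).

## Numerical choices and degenerate inputs

- Internal units: nm, ps, kJ/mol, K, amu; angles stored in radians,
  reported in degrees; Å↔nm conversion only at the PDB boundary.
- State classification is strict: closed-like iff RG < 1.6 nm AND
  angle < 80°; sub-boundaries closed/half-closed at 70° and
  open/half-open at RG 1.7 nm (configurable).
- Kabsch superposition requires ≥3 non-collinear atoms (rank check);
  rotations are proper (det +1) via `scipy.spatial.transform`.
- Single-frame trajectories are rejected for RMSF/covariance; empty
  residue selections, ragged tables, malformed ATOM records (reported
  with their line number), zero total mass and divergent integrator steps
  (|Δθ| > π/4) all raise immediately.
- Geometry calibration accepts on the residual (≤1e-3 nm) rather than the
  root-finder's progress flag; the (radius, length) trade-off direction
  is nearly degenerate.

## What the surrogate does and does not show

The generator emulates: two-state hinge thermodynamics with the published
well locations/depths, a dominant collective motion localized on the
hairpin, closed-state arm–core contacts, and measurement noise on every
bead.  It does **not** emulate solvent, secondary structure, anharmonic
core flexibility, multi-pathway transitions, or any coupling between the
hinge and internal core modes.  Green tests certify the estimators and
the engine against planted truth at desk scale; they say nothing about
force-field accuracy on the real protein.

## Known limitations

- One-dimensional CVs only; no walls, multiple walkers or adaptive hill
  widths.
- The hinge dynamics are overdamped and one-dimensional; kinetic
  quantities (rates, transition paths) are not meaningful, only the
  stationary landscape.
- The running-offset reweighting scheme needs a burn-in on trajectories
  with a long pre-equilibrium transient (see above).
- PDB support covers single-chain multi-model ensembles (ATOM/MODEL/
  ENDMDL); mmCIF, altlocs and insertion codes are out of scope.
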