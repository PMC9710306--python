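# Methods

This note documents the models, numerical choices, and limitations behind
the package, in the spirit of the methods documentation of mature
simulation libraries.

## Model overview

The workflow treats reaction discovery as constrained conformational
exploration. One internal coordinate q‡ (distance in Å; angle or dihedral
in degrees) is held at a ladder of out-of-equilibrium values
q‡₀ < q‡₁ < … < q‡_N (or the reverse, for compression). At each activated
value the system is a *constrained* local-minimum problem: metadynamics
explores the orthogonal space, and each distinct activated conformer seeds
a pair of relaxed scans (forward to q‡_N, backward to q‡₀) whose stitched
union is a full reactant → product trajectory. Nothing in the method
assumes knowledge of products; they emerge from the scans.

Internal units are Hartree/Å/fs/amu/K; all user-facing energies are
kcal/mol (conversion fixed at 627.509474).

## Energy backends

Backends implement `evaluate(geometry) -> EnergyGradient` and are pure
functions of the geometry.

**Pairwise-Morse toy backend.** Each element pair (Z₁, Z₂) carries
(D_e, a, r_e); the pair energy D_e[(1−e^{−a(r−r_e)})²−1] is multiplied by a
cubic smoothstep that is exactly 1 below 0.9·r_cut and reaches 0 with zero
slope at r_cut (default 8 Å), so the potential is C¹ everywhere, a bound
pair at r_e contributes exactly −D_e, and separated fragments cost exactly
zero. Pairwise Morse sums support bond breaking and forming, which is all
the workflow needs; they make no claim to quantitative chemistry. Missing
pair parameters are an error naming the pair, never a silent zero.

**External engine adapter.** A subprocess/file adapter for semi-empirical
engines: geometry out as XYZ, energy + gradient back as a two-section plain
text file (`energy <Hartree>` then one gradient row per atom in
Hartree/Å). Results are cached on a coordinate hash rounded to 1e-6 Å; all
engine files are kept per-call for audit. Engine failures raise a
structured error carrying exit code and stderr; the pipeline records and
skips the affected trajectory instead of aborting the run. Different
engine versions can give different surfaces; the adapter reports what the
engine returns and does not attempt to normalize across versions.

## Superposition RMSD and its gradient

RMSD between snapshots is the minimum over rigid-body superpositions
(Kabsch, via proper-rotation alignment), all atoms, unweighted, with atom
order fixed by input — snapshots of one simulation always have tracked
atom identity, so permutation matching would only blur distinct
conformers. A `heavy_only` flag restricts the comparison to non-hydrogen
atoms. At the optimal superposition, the derivative of the RMSD through
the rotation and translation vanishes, giving the analytic per-atom
gradient (x_c − R y_c)/(N·Δ). The gradient is singular at Δ = 0; below
Δ = 1e-6 Å the zero vector is returned, which is consistent because the
bias kernel's chain-rule prefactor 2αΔ vanishes at the same point.

## Metadynamics

The bias is V = Σᵢ k·exp(−α·Δᵢ²) over stored snapshots. Defaults
k = 0.002 Hartree × N_atoms and α = 0.8 Å⁻², with a snapshot added every
50 fs up to 100 kernels (the dynamics continues after the cap; the bias
simply stops growing). These magnitudes follow common practice for
RMSD-kernel conformer generation and are exposed in `BiasParams`.

Integration is velocity Verlet with a Berendsen thermostat (τ = 50 fs,
default 300 K). The default timestep is 0.5 fs: the toy systems contain
hydrogen on stiff Morse bonds with ~12 fs periods plus harmonic
restraints, and 1 fs sits at the edge of Verlet stability there. Initial
velocities are Maxwell–Boltzmann from the run seed with the
centre-of-mass drift removed; temperature 0 starts from rest with the
thermostat disabled. A non-finite or runaway potential energy (more than
10 Hartree above the start) truncates the run, returning the snapshots
collected so far, flagged.

The activating coordinate is held by a harmonic restraint (no constraint
projection — restraint forces are differentiable and engine-agnostic).
The driver uses 8 Hartree/Å² during MD: on the steep slope of a stretched
bond the static offset of a restraint is |F|/k, and 8 Hartree/Å² keeps
snapshots within ~0.05 Å of the target at 300 K.

An optional quartic confining wall about the initial centroid
(`MDParams.wall_radius`) keeps loosely bound fragments of a reactive
complex from drifting apart during sampling, as is standard in reactive
conformer generation; the toy-system runs enable it at 4–5 Å.

## Constrained optimization and scans

Constrained minimization enforces internal-coordinate targets as exact
equality constraints (SLSQP with analytic constraint gradients;
unconstrained problems use L-BFGS-B). An exact-constraint formulation was
chosen over a stiff-restraint penalty because a penalty leaves a residual
|measure − target| ≈ |F|/k that contaminates scan energies at any
reasonable stiffness; with equality constraints, a relaxed scan of a
separable potential reproduces its closed-form profile to numerical
precision. Convergence is reported when the constraint-projected gradient
is below 5e-4 Hartree/Å (iteration cap 500) and every constraint is within
0.01 Å / 0.5°. Non-converged scan frames are kept but flagged; flagged
frames propagate into an `approximate` marker on any reaction row whose
best transition structure came from one. Distance gradients are analytic;
angle and dihedral gradients use periodicity-safe central differences on
the few defining atoms.

Scan steps default to 0.1 Å / 5°. The toy-system study runs use 0.05 Å:
the transition-structure guess is the discrete maximum of the scanned
profile, whose error grows with the square of the step, and on the toy
surface (curvature ≈ 1 Hartree/Å² near the saddle) 0.1 Å would contribute
~0.8 kcal/mol — most of the 1 kcal/mol agreement demonstrated against the
oracle — while 0.05 Å contributes ~0.2.

## Ensemble pruning

Snapshots are constrained-minimized, then deduplicated: two conformers are
the same only if RMSD < 0.125 Å *and* |ΔE| < 0.05 kcal/mol *and* all
finite rotational constants agree within 1%. The lower-energy member of a
duplicate pair is kept; exact ties keep the earlier snapshot
(deterministic). Members more than 35 kcal/mol above the ensemble best are
dropped. Comparison happens after re-optimization, so thresholds act on
relaxed structures. Rotational constants come from the rigid-rotor
formula on standard atomic masses; a linear molecule reports an infinite
sentinel for the zero-moment axis, and duplicate detection compares only
the finite constants.

## Reaction detection and the table

Bonds are perceived geometrically: atoms bond iff their distance is at
most 1.2 × the sum of covalent radii (standard table). The molecular
graph keeps single bonds only — no bond-order perception — with formal
charges distributed by a valence-rule pass (over-valent electronegative
atoms take +, residual anionic charge goes to under-valent atoms in the
order O, S, halogens, N, …) and remaining unfilled valence recorded as
unpaired electrons. Fragments are canonicalized independently
(RDKit), sorted lexicographically and dot-joined, so bimolecular
complexes compare equal regardless of atom order; a fragment whose
valence pattern cannot be sanitized falls back to a deterministic
`!`-prefixed formula string and is logged. With `drop_metals`, d-block
atoms are removed before perception so ligand rearrangements around a
metal centre do not register as spurious reactions.

Trajectory minima use a weak-inequality local-minimum rule with endpoints
included when the profile rises away from them (a constant profile yields
the endpoints only). Each minimum is re-optimized without constraints; if
it relaxes to a different species, the relaxed species is used and the
event is logged as an unstable intermediate. Consecutive minima with
different SMILES give one event; SMILES are compared between *consecutive*
minima rather than endpoint-vs-all so multi-step cascades appear as
chained events. The transition-structure guess is the highest-energy frame
strictly between the two minima (ties take the earliest frame).

Aggregation keys rows by the (reactant, product) SMILES pair. The barrier
reference is the single most stable conformer of the step-1 reactant
ensemble for every row, so barriers across the table are comparable;
ΔE ≥ 0 is guaranteed for the barrier but not for the reaction energy
(exothermic and endothermic products are both legal). Tables expose a
`filtered(max_barrier_kcal=35)` view — the conventional feasibility cap
for this kind of semi-empirical screen — which the toy studies use to
separate the discovered exchange from dissociation channels whose
estimated barriers are near the bond-dissociation energy.

## Schedule, budget, and reproducibility

The activated values default to stretch factors {1.1, 1.2, 1.3, 1.5} of
q‡₀ with q‡_N = 2.5·q‡₀; all overridable, including as absolute values.
Scheduled metadynamics time is `md_time_per_atom_ps × N_atoms` (default
0.3 ps/atom), making sampling effort proportional to system size by
construction. The trajectory budget caps stitched trajectories per run;
every launched trajectory lands in exactly one ledger bucket (completed /
flagged / failed). Per-trajectory seeds derive from the run seed as
`(seed·1000003 + (i+1)·8191 + (c+1)·127) mod (2³¹−1)` for ladder index i
and conformer index c — reproducible and parallel-safe. With a fixed seed
the whole run, including the serialized reaction table, is bitwise
reproducible.

## The synthetic test systems and what they show

`make_collinear_exchange` builds Cl–H + Br on pairwise Morse terms: the
two bonds share (D_e = 0.15 Hartree, a = 1.8 Å⁻¹, r_e = 1.4 Å), the
product bond optionally deepened by an asymmetry factor, and the terminal
pair carries a soft Morse (D_e/6, 0.61·a, 3.29·r_e) that is net repulsive
over the sampled region — so the collinear approach is the minimum-energy
arrangement, the 2-D (r_AB, r_BC) surface has exactly two wells and one
saddle (~11.5 kcal/mol for the symmetric defaults), and the loose
reactant complex is a genuine interior minimum. The terminal elements are
required to differ so the exchange is visible to SMILES comparison even
when the potential is symmetric. `make_torsional_chain` builds a 4-atom
chain whose weak 1–4 term creates two mirror torsional wells at ±60° —
the smallest system where a conformer search has something to find.

The oracles are deliberately independent of the pipeline: the grid oracle
evaluates the collinear surface on a dense grid (default 300²), finds the
minimax barrier between the two lowest wells by adding cells in ascending
energy order until the basins connect (exact on the grid graph), and
polishes saddle and wells on the continuous surface; it errors if the
regime has no saddle or the saddle shifts under 2× grid refinement. The
Müller–Brown function is included as a standard optimizer testbed.

Passing these tests shows the machinery is correct — constraints are
enforced exactly, the bias matches its definition, trajectories find the
known saddle within 1 kcal/mol, bookkeeping is exact and reproducible. It
does not show chemical realism: toy Morse sums have no electronic
structure, no angular valence forces, and three-atom systems have trivial
conformational spaces. Real discovery requires an external quantum
chemistry engine behind the adapter.

## Known limitations

- Bond orders and stereochemistry are not perceived; reaction detection is
  by constitution only. Tautomers that differ only in bond order with the
  same connectivity would not be distinguished.
- Charge assignment is heuristic; exotic valence patterns fall back to
  formula sentinels (detected and logged, but such frames cannot be
  attributed to a specific species).
- Transition-structure guesses are scan maxima, not verified saddle
  points; no eigenvector-following, NEB, or IRC is performed.
- The harmonic MD restraint permits ~0.05 Å excursions of the activating
  coordinate at 300 K; the subsequent constrained re-optimization removes
  this slack before energies are compared.
- Tautomer/protonation-state enumeration is not automated; alternative
  input structures are separate runs.
- Periodic systems and isotope masses are out of scope.
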