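# Methods

This note records the models, conventions and numerical choices behind
`bzrmd`, and what the synthetic-data tests do and do not demonstrate.

## Structures, numbering and selections

Structures are read from PDB files via gemmi into a flat list of atom
records (chain, residue name/number, atom name, coordinates in Å, B-factor,
element). Residue numbers are the author numbering from the file and are
never renumbered: published residue identities (Glu37, Arg40, Asp64 of the
BZR basic region; Glu300/Glu304 of the MBP chaperone) are author numbers.
Alternate conformations are resolved to a single conformer per atom name —
highest occupancy, ties broken toward altloc "A" — so downstream geometry is
deterministic. Waters are kept by default (they carry the water-mediated
hydrogen bonds); `keep_waters=False` strips them.

Trajectories are multi-model PDB files, or a whitespace frame table
(`natoms frame_interval_ps` header, one row per atom per frame) for synthetic
fixtures. All frames share one topology; the frame interval defaults to
10 ps, the typical MD snapshot spacing.

Selections are a small expression language over the fields an analysis
needs — `chain`, `name`, `resname`, `resid`, and the bare classes `protein`,
`nucleic`, `water`, `hetatm`, `backbone`, combined with and/or/not. Resolution
is a pure function of (model, expression) and preserves file order.

## Superposition and RMSD

Kabsch superposition minimizes RMSD over proper rotations and translations
via the SVD of the cross-covariance of the centered point sets; reflections
are excluded by flipping the sign of the smallest singular value when
det < 0. Point sets with fewer than 3 points, or whose two smallest
covariance singular values vanish (collinear sets, rotation about the common
line undetermined), are rejected as ill-conditioned. The fit is unweighted —
no mass or B-factor weights — because the validation protocol specifies only
which atoms are aligned, not a weighting.

Trajectory RMSD fits every frame independently to the fixed reference on the
fit selection and reports RMSD on each measure selection of the fitted
frame. There is no progressive or average-structure fitting: the question
asked is "how far is each snapshot from the crystal", so the crystal is the
only reference. Frame-series SDs (RMSD and tilt alike) are population SDs
(divide by n): they describe the spread of the recorded frames themselves.

## Helix axes and the tilt angle

The discriminating statistic is the crossing angle between the two
DNA-recognition helix axes of a dimer: ~78° for the BZR architecture versus
50–65° for canonical bHLH factors.

An axis is fitted to an inclusive residue range (≥ 6 residues, two helical
turns) as the dominant principal axis of the Cα positions **after a one-turn
(4-residue) sliding-window average**. The averaging matters: a raw principal
axis of a short helix is tilted by the helical winding itself — with a
2.3 Å radius and only ~3 turns the net circular excursion biases the axis by
2–7° (measured on ideal geometry) — while the window average cancels the
winding phase and brings ideal-helix recovery below 0.3°. The axis sign is
fixed to point from the first-residue Cα toward the last (residue numbers,
not file order), and the anchor is the Cα centroid.

The tilt angle is folded: θ = arccos |û_a · û_b| ∈ [0°, 90°]. Folding removes
the N→C orientation ambiguity between axis conventions; every value in the
regime of interest (50–78°) is below 90°, so the fold never changes a
reported number. Tolerance for matching a published crystal value is ±3°,
absorbing axis-convention differences.

`detect_helices` proposes ranges as maximal runs with Cα(i)→Cα(i+4)
distances in [5.0, 6.5] Å covering ≥ 6 residues — a one-turn distance
window, not a DSSP replacement. Recognition-helix ranges for real entries
are configuration inputs; the documented procedure for choosing them is to
run `detect_helices` on each protein chain and take the DNA-proximal helix
(minimum mean Cα-to-phosphorus distance). The deposited reference entries
could not be bundled here, so the defaults shipped in tests are synthetic
stand-in dimers built at the published regimes (78° and 55°); applying the
procedure to the real entries is a one-command exercise for a user with the
files.

## Contacts and occupancy

Geometric criteria are declared conventions (the source analyses state
none), fixed before any comparison and overridable at every call site:

- **Hydrogen bond**: donor–acceptor heavy-atom distance ≤ 3.5 Å between
  N/O atoms with standard donor/acceptor roles (amino acids,
  deoxynucleotides including phosphate/sugar oxygens, water). The D–H···A
  angle ≥ 120° test applies only when explicit hydrogens are present —
  crystal structures lack them, MD frames may carry them.
- **Salt bridge**: Arg NE/NH1/NH2, Lys NZ, His ND1/NE2 versus Asp OD1/OD2,
  Glu OE1/OE2 or phosphate OP1/OP2, ≤ 4.0 Å.
- **van der Waals**: heavy-atom distance ≤ r₁ + r₂ + 0.4 Å with radii
  C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å (fixed internal table,
  overridable).
- **Water bridge**: a water oxygen hydrogen-bonded (same criteria) to at
  least one atom in each group; the event records both bridged atoms, the
  longer leg and the water.

In combined interface reports each atom pair appears under exactly one kind
with precedence salt_bridge > hbond > vdw. Interface reports group events by
cargo residue and attach per-chain mean B-factors, supporting
mobility comparisons between crystallographic assemblies.

Occupancy is the fraction of frames in which a named donor–acceptor pair
satisfies the distance criterion, reported per pair/chain/run in a tidy
table (columns pair, chain, run, fraction, n_frames) — the numeric form of
the usual replicated-MD occupancy color matrix. The estimator is exact
counting; tests require bit-exact agreement with a brute-force per-frame
recount and with the generator's recorded on-counts.

## Free-energy estimators

Energies are reduced (kT = 1) internally; `kt_to_kcal_per_mol` converts at a
stated temperature. λ schedules are uniform with endpoints 0 and 1; the
default 21 states give 19 intermediates and 20 adjacent pairs ("21 steps" in
protocol parlance is read as 21 states; both counts are exposed on the
schedule object).

Per adjacent pair, the Bennett acceptance ratio solves the maximum-
likelihood self-consistency condition
Σ_F f(u_F − C) = Σ_R f(u_R + C), f(x) = 1/(1+eˣ), C = ΔF − ln(n_F/n_R),
by bracketed Brent root-finding (the imbalance is monotone in ΔF, so the
root is unique), initialized at the Zwanzig estimate, stabilized with
log-sum-exp/sigmoid forms. Failure to bracket within ±50 kT is reported as a
phase-space-overlap failure whose remedy is a finer schedule. The per-step
uncertainty is the standard BAR asymptotic variance; the total is the sum of
steps with root-sum-square uncertainty. The one-sided Zwanzig estimator
(−ln⟨e^{−u}⟩) is kept as an independent cross-check — tests verify BAR's
smaller squared error and its exact antisymmetry under direction reversal,
which Zwanzig lacks.

The binding cycle is ΔΔG = ΔG(complex, 1→2) − ΔG(free DNA, 1→2); positive
values mean the substitution weakens binding. The replicate protocol (six
independent repeats by default) reports mean ± sample SD (ddof = 1) across
replicates as the headline uncertainty — replicate scatter, not the
asymptotic formula, is what the protocol trusts. Equilibration is mirrored
as a discard fraction (default: first 50% of each state's samples dropped,
the "last half" rule).

Base-substitution bookkeeping operates on a 6-position motif string
(canonical G-box CACGTG): substitutions must stay within a chemical class
(purine↔purine or pyrimidine↔pyrimidine) and automatically record the
complementary change on the paired strand (C1→T1 implies G→A at the paired
position). Class-crossing requests are rejected.

## Synthetic generators and what passing tests show

Generators plant known ground truth and record it in metadata:

- Ideal helices use textbook α-geometry (rise 1.5 Å, twist 100°, radius
  2.3 Å); pairs are built by rotating the second helix's generating axis by
  an exact crossing angle about a perpendicular hinge.
- Noisy trajectories add i.i.d. isotropic Gaussian noise; tilt-fluctuation
  trajectories rock helix B rigidly about the fixed hinge with Gaussian
  angle deviations, recording per-frame true angles. The study-condition
  defaults mirror the reference regime: 78° mean, 2.3° angular SD, 1000
  frames per run, three runs.
- Hydrogen-bond toggles place the acceptor at 2.9 Å (on) or 5.5 Å (off)
  by seeded Bernoulli draws, recording the exact on-count.
- Harmonic alchemy draws exact Gaussian samples from k(λ) = k0 + λ(k1−k0)
  with analytic ΔF = ½ ln(k1/k0); the toy binding system pairs a flat free
  leg with a stiffening complex leg (defaults k 1 → 4, so
  ΔΔG = ½ ln 4 ≈ 0.6931 kT), six replicates from distinct seeds.

All randomness flows through explicit seeds; identical spec + seed is
bitwise reproducible.

What the synthetic tests demonstrate: the estimators are correct — optimal
superposition, exact angle recovery, exact occupancy counting, unbiased BAR
with calibrated uncertainties, closed thermodynamic cycles. What they do not
demonstrate: anything about real conformational ensembles. Gaussian
coordinate noise has no correlated motions, the toggle series has no
intermediate geometries, the harmonic Hamiltonians have perfect state
overlap, and Cα-only traces carry no side chains. Agreement of an estimator
with its synthetic ground truth therefore validates the computation, not the
physics of any particular system.

Problem sizes in the test suite and acceptance script (12-residue helices,
hundreds to a thousand frames, 10⁴ samples per λ state, six replicates)
were chosen to hold Monte-Carlo error well below every asserted tolerance
while keeping a full run in seconds.

## Known limitations

- No DSSP-grade secondary structure, helix curvature splines, or DNA groove
  geometry; the axis model is a straight line per helix.
- Contact detection has no π-stacking/cation-π classes and no energy
  scoring; symmetry mates are not generated (interfaces are analyzed only
  between chains present in the file).
- The free-energy module has no soft-core potentials, no multi-state MBAR,
  and no molecular topology — it estimates from sampled reduced-energy
  tables.
- mmCIF writing is out of scope; PDB fixed-width fields limit coordinates
  to |x| < 10 000 Å.
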