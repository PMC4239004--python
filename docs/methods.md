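# Methods

This note records the models implemented in `funnelpot`, the parameter
choices that matter, and the design decisions taken where more than one
reasonable construction existed.

## Structure model and preprocessing

A model is a Cα trace: a one-letter sequence, one 3-vector per residue
(Å), and a per-residue backbone-completeness flag (Cα, N, C and O all
present).  Decoy collections are made index-consistent in two steps:
residues with incomplete backbones are removed from every model, then each
decoy sequence is globally aligned to the native with identity scoring and
end gaps only, and unmatched *leading/trailing* residues are trimmed from
whichever side carries them until all sequences are identical.  Internal
mismatches or gaps are rejected with an error naming the decoy: end
trimming is the only repair this pipeline performs, because silently
resolving an internal edit would misalign every downstream pair quantity.
Under this scoring the optimal alignment is a relative shift, so the
implementation enumerates shifts; ties between equally long mismatch-free
overlaps go to the smaller absolute shift.  The native is subjected to the
same completeness rule as the decoys (symmetric treatment); the
alternative — trusting the native unconditionally — would let a native
residue with no decoy counterpart survive harmonization.

PDB input goes through gemmi: first MODEL only, first protein chain unless
one is named, HETATM ignored, altlocs resolved by occupancy then file
order, non-standard residues mapped to their standard parent where
unambiguous (MSE→M, SEC→C, ...) and dropped with a warning otherwise.
Written PDB files carry placeholder N/C/O positions at fixed offsets from
the Cα for backbone-complete residues so the completeness flag survives a
round-trip; only Cα coordinates are ever consumed.

## Distance measures

**RMSD** uses the closed-form optimal proper rigid superposition (Kabsch,
via scipy's `Rotation.align_vectors`); reflections are excluded and the
degenerate (collinear) case takes the minimal-rotation convention.

**GDT-TS** averages, over cutoffs 1/2/4/8 Å, the largest fraction of
residues superposable within the cutoff.  The maximal-subset search is not
standardized anywhere; this implementation seeds candidate superpositions
from every contiguous fragment of lengths 3, 5, 7 and N (start stride 2
for N > 200) and refines each by re-superposing on the current inlier set
until stable (≤ 10 rounds), keeping the best inlier count over all seeds —
a deterministic variant of the LGA-style search.  Against an exhaustive
all-fragment enumeration on 20-residue chains the result agrees within
0.05.  GDT-TS and Q are similarities; evaluation always uses their starred
distance forms GDT-TS\* = 1 − GDT-TS and Q\* = 1 − Q.

**Q\*** counts native contacts (Cα distance ≤ 9 Å) lost by the decoy:
Q = sc/(sc + lc) over the native's contact set only, so contacts gained by
the decoy never enter.  A native with zero contacts gives Q = 1 (nothing
to lose) rather than 0/0.

**FlexE / MT** sum over the *native* structure's contact pairs — using
one fixed map keeps the energies well defined for every native-decoy
comparison — with per-pair terms (k/2)Δ² and (k/b²)(e^(−bΔ) − 1 + bΔ),
Δ = d^D − d^N.  The Toda form satisfies the three properties that pin it:
value and slope zero at Δ = 0, second-order Taylor expansion equal to the
harmonic term, and a stronger penalty for compression than extension.
Defaults: k = 1, b = 0.5, threshold 9 Å.

All contact maps (Q\*, FlexE/MT, consensus, PPE) use a minimum sequence
separation |i − j| ≥ 3: shorter-range Cα distances are fixed by covalent
geometry and carry no discriminative signal.  The separation is exposed as
configuration.

## Spline pair potential

Each of the 210 unordered amino-acid-type pairs has an interaction
f(d) = Σ<sub>p</sub> θ<sub>p</sub> B<sub>p</sub>(d) on a uniform cubic
B-spline basis with integer knots 1..12 Å — the unique uniform cubic basis
with compact support [1, 12] Å and exactly 8 degrees of freedom.  The
basis is a partition of unity on [4, 9] Å (the freely modeled window) and
decays C²-smoothly to zero at both ends; distances below 1 Å contribute
nothing (physically irrelevant for Cα pairs; no extra clash term is
added).  The implementation evaluates the closed-form cardinal cubic
pieces; tests check it against scipy's independent de Boor evaluation at
1e-12.  Pair ordering is lexicographic over sorted one-letter codes,
giving the canonical bijection onto 0..209.

PPD sums f over all counted pairs of a model; PPE restricts the sum to a
consensus contact map S.  PPE includes no contribution from
non-consensus pairs — the narrower reading of the ensemble potential — so
PPE with a full S reduces exactly to PPD.

## Consensus contact map

Starting from the full ensemble: compute the contact-frequency matrix M
over the currently selected decoys, threshold S = [M ≥ μ] with μ = 0.25,
then select the ⌈0.25 n⌉ decoys *of the full ensemble* closest to S in
upper-triangle Hamming distance (ties by decoy order) and repeat until S
is unchanged (max 20 rounds; convergence typically takes 2–3).  Selecting
from the full ensemble rather than the shrinking subset keeps the subset
size stable and makes the iteration a well-defined fixed-point search; the
alternative reading (progressively reducing the pool) collapses the
ensemble geometrically.  Ensembles with fewer than 8 decoys get a
single-pass map, since 25% of so few decoys is degenerate.

## Training

Energies are linear in the coefficient vector X (1680 entries), so the
energy gap of decoy j of protein i is an inner product
ΔE<sub>ij</sub> = φ<sub>ij</sub>·X with a precomputed feature vector
(decoy basis sums minus native basis sums, restricted to the consensus map
in PPE mode).  Training minimizes

    Σ_ij (φ_ij·X − c_i d_ij)² + β ‖X‖²   subject to   c_i ≥ c_bound

jointly over X and the per-protein proportionality constants c.  The lower
bound (default 1) excludes the trivial solution X = 0, c = 0 and fixes the
energy scale; no sign constraint is placed on θ (pair interactions may be
attractive or repulsive).  The problem is a convex bound-constrained
linear least-squares problem and is solved with `scipy.optimize.lsq_linear`
(variables stacked as (X, c), ridge rows √β·I on X).  An
alternating-minimization solver — ridge solve for X, closed-form
c<sub>i</sub> = max(c_bound, Σ<sub>j</sub> ΔE<sub>ij</sub> d<sub>ij</sub> / Σ<sub>j</sub> d<sub>ij</sub>²) —
serves as an independent cross-check; both reach the same objective to
1e-5 relative.  β defaults to 1e-3 × (number of rows) when not given;
rows are not reweighted per protein (proteins with more decoys weigh
more), which matches the plain sum in the objective.  Targets that are all
(effectively) zero make the funnel slope unidentifiable and raise a
degenerate-input error.

## Synthetic data

`gen_native` grows a self-avoiding random Cα walk: exact 3.8 Å virtual
bonds, non-adjacent pairs ≥ 4.0 Å, a centroid-pull bias plus a
radius-of-gyration acceptance bound R<sub>g</sub> ≤ 3.0 · N^(1/3) Å to
keep chains globular (overly extended chains have almost no contacts and
overfit trivially).  `gen_decoys` adds per-coordinate Gaussian noise
smoothed with a window-3 moving average along the chain (correlating
neighbour displacements roughly preserves bond lengths while deforming the
global fold) and then a random rigid motion, so extrinsic and intrinsic
measures diverge the way they do on real decoys.  The default noise grid
is σ ∈ {0.5, 1, 2, 4} Å, evenly splitting the decoy budget.  One integer
seed streams all randomness; every pipeline stage is bit-reproducible from
it.

What the generator does *not* emulate: torsion-angle geometry, secondary
structure, sequence-dependent packing, or sampling bias of any real decoy
generator.  Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted structure, not transferability of
trained potentials to real proteins.

**Planted funnels.**  For recovery experiments the target distances are
d<sub>ij</sub> = max(ε, φ<sub>ij</sub>·θ\*) with ε = 1e-6 (distances must
be nonnegative; the floor is used rather than resampling).  Because
φ·θ\* is linear in the coordinate perturbation, its sign is symmetric for
small deformations no matter the choice of θ\* — a planted target is only
a genuine funnel when the floor stays inactive.  Two defaults follow from
that requirement: θ\* is a uniform attractive well (every coefficient
−0.5), whose induced gap counts pairs pushed out of interaction range —
a smooth contact-loss distance; and the recovery experiment uses the
larger-deformation grid σ ∈ {4, 5, 6, 8} Å, where the systematic expansion
drift (∝ σ²) dominates the linear spread (∝ σ) and fewer than ~3% of
targets touch the floor.  The residual floor activation sets the recovery
ceiling: the trained potential tracks the exact-recovery oracle
corr(φ·θ\*, d) to within ~0.01 on held-out decoys.

## Problem sizes and numerics

The recovery experiment runs 10 proteins × 40 residues × 100 training
decoys (1000 rows × 1680 features) plus 100 held-out decoys per protein;
it completes in well under a minute on one CPU.  The QP is solved to
lsq_linear's default TRF convergence with tol 1e-12; c values at the
active bound are snapped to it to absorb solver round-off.  Argmin ties in
R-scores break to the first decoy index; undefined correlations and
R-scores (zero variance, all-equal distances) are reported as flags,
excluded from aggregation, and counted.  Serialization of parameter tables
uses repr-precision decimal text and round-trip float parsing, making
TSV/JSON round-trips bit-exact.

## Known limitations

- GDT's fragment-seed search is a deterministic approximation; it can in
  principle miss the true maximal superposable subset, though the
  exhaustive cross-check bounds the error at small N.
- PPE's restriction to consensus pairs and the c<sub>i</sub> ≥ 1 scale
  constraint are reconstructions of designs that admit variants; both are
  isolated behind configuration.
- Trained coefficients here are only as meaningful as the synthetic
  ensembles they are trained on; no claim is made about performance on
  experimental decoy sets.
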