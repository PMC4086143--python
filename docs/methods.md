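# Methods

`protstab` predicts the folding free-energy change ΔΔG (kcal/mol) of a
single point mutation from the wild-type structure alone. This note
documents the model, its parameters, the synthetic data the tests run on,
and the numerical and design choices a maintainer would want stated.

## Structure model and input policies

PDB files are parsed with Biopython; the in-memory model is an ordered list
of residues (author numbering plus insertion code, never renumbered)
carrying ordered atoms with coordinates. Policies layered on the parser:
only the first model of a multi-model (NMR) file is used; waters and hetero
groups are excluded except selenomethionine, which is kept as methionine
with SE renamed SD; alternate locations collapse to the highest-occupancy
conformer, ties broken by file order; non-standard residues are dropped
with a warning. Mutations are given as `<WT><pos><MUT>` plus a chain, and
the wild-type letter is validated against the structure. Mutant structures
are represented by a placeholder (label change + side-chain truncation to
CB): every feature of the predictor is computed from the wild-type
environment plus residue-type deltas, so no rotamer modelling is attempted
(a declared non-goal).

## Environment features

**Solvent accessibility.** Shrake–Rupley point sampling with a probe of
1.4 Å on a deterministic Fibonacci (golden-angle) sphere lattice; van der
Waals radii C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80, Se 1.90 Å
(config-overridable). The default density is 7680 points per atom: the
binary accessible/buried quadrature converges like n^(−1/2), and this
density is what keeps per-residue areas stable to better than 0.5% under
rigid rotation (at 960 points the variation reaches ~1.8%). RSA divides a
residue's area by a packaged Gly-X-Gly maximum-accessibility table
(theoretical values of Tien et al. 2013) and is clamped to [0, 1].

**Secondary structure.** A deliberately coarse 3-state assignment from
backbone dihedrals: helix for φ ∈ [−120°, −30°] and ψ ∈ [−80°, −5°] over at
least 3 consecutive residues; strand for φ ∈ [−180°, −45°] and ψ ∈ [45°,
180°] (or ψ ≤ −170°) over at least 2; everything else, including chain
termini with undefined dihedrals, is coil. The consensus model consumes
only this coarse class, so a DSSP-faithful 8-state assignment is out of
scope. All windows are config keys.

**Side-chain hydrogen-bond satisfaction.** True iff every side-chain N, O
or S atom of the residue has a polar heavy atom (N or O) of a different
residue within 3.5 Å; residues without such atoms are vacuously satisfied.
This heavy-atom distance criterion (no angles, no explicit hydrogens) is a
stated convention, reported as context rather than used as a model feature.

## Pharmacophore typing and distance signatures

Each heavy atom of a standard residue maps to one or more of eight classes
(hydrophobic, positive, negative, hydrogen acceptor, hydrogen donor,
aromatic, sulphur, neutral) via a packaged table following standard
conventions (carboxylate oxygens negative + acceptor, Lys/Arg/His cationic
nitrogens positive + donor, F/Y/W/H ring atoms aromatic with ring carbons
also hydrophobic, backbone N donor — except proline — and backbone O
acceptor, Cys/Met sulphur, amide/carboxylate/guanidinium carbons neutral).
Multi-membership is allowed, so residue vectors are independent counts, not
a partition; the change vector of a mutation is wild type minus mutant,
component-wise, and backbone atoms are included.

The signature of a mutation site takes all heavy atoms of residues with any
atom within 10 Å of the mutated residue and counts, for each unordered
class pair (36 categories) and each cutoff in a 0–10 Å sweep at 0.5 Å
steps, the atom pairs within the cutoff in which the two atoms carry the
two classes. Counts are cumulative in the cutoff, hence monotone, and
depend only on distances, hence exactly invariant under rigid motion.
Flattening is shells-major, category-minor, and fixed. All constants are
config keys; tests never depend on their values.

## Substitution score and RSA calibration

Environments form a 9-letter alphabet: {helix, strand, coil} × {buried
rsa < 0.07, intermediate 0.07 ≤ rsa < 0.25, exposed rsa ≥ 0.25}. An
environment-specific substitution table P(aa | env) is estimated from
labelled residue observations with additive pseudocounts (default 1.0), the
background P(aa) from the pooled counts. The raw score of a mutation is

    raw = scale · [ ln P(mut|env) − ln P(wt|env) − (ln P_bg(mut) − ln P_bg(wt)) ]

with the folded state modelled by the environment-conditional propensities
and the unfolded state by the background; `scale` defaults to 1 kcal/mol
per log-unit and any linear rescaling is absorbed by the calibration. The
score is antisymmetric in (wt, mut) and exactly zero for identity
mutations. Real substitution tables derived from curated structural
alignments of homologous families are not bundled; the package estimates a
demonstration table from synthetic environment-labelled residues with
plausible biases (buried↔hydrophobic, exposed↔polar, per-state residue
preferences) and loads user-supplied tables from TSV.

Calibration fits an M5-style model tree on (raw, RSA) against experimental
ΔΔG: binary splits, least-squares linear models at the leaves, and
bottom-up pruning that merges two sibling leaves whenever the merged linear
model's leave-one-out error (hat-matrix identity) is not worse. Split
selection maximises the reduction in *leaf-model residual* SD rather than
target SD: a split that changes the slope of the ΔΔG–raw relationship
(e.g. an RSA gate) barely changes the target SD and is invisible to the
classic criterion, while the residual criterion finds it and also collapses
exactly-linear data to a single leaf. Stopping: depth 4, minimum leaf 20,
or best reduction below 5% of the root SD. Up to 32 quantile-thinned
candidate thresholds per feature bound the fit cost.

## Consensus regressor

The consensus feature vector is fixed-order and 13 wide: the signature
component prediction, the calibrated substitution score, the 3-state
secondary-structure one-hot and the 8-component pharmacophore change. Both
the signature component and the consensus are ε-SVRs with RBF kernel,
solved by libsvm's SMO (via scikit-learn) behind a thin model class that
owns per-feature standardisation (fitted on training data only — which also
makes the fit invariant to affine feature rescaling), JSON persistence of
the support vectors, dual coefficients, intercept and standardisation
statistics (no pickled state; predictions reproduce bit-for-bit across
machines), and dual-feasibility diagnostics (Σ(α−α*) = 0, |α| ≤ C, asserted
in tests). Hyperparameters default to a 5-fold cross-validated grid
(C ∈ {1, 10, 100}, γ ∈ {0.01, 0.1, 1}, ε = 0.1, Pearson-r scoring, fixed
fold seed recorded in the bundle); explicit values bypass the search.

Training fits the calibration tree and the signature component, then the
consensus on **out-of-fold** component predictions (5 folds): feeding
in-sample component predictions to the consensus would let it learn their
optimistic training accuracy rather than their generalisation. The
signature-component hyperparameters are selected once on the full training
table before the stacking loop; this mild shortcut trades a small
optimistic bias for a ~5× cheaper search and did not measurably affect the
held-out results. The saved bundle is a single versioned JSON carrying the
substitution table, the tree, both SVRs, the sign convention, the training
position keys (for blind-split warnings) and the configuration hash of the
feature settings.

The sign convention is explicit because conventions differ between tools:
internally and by default, negative ΔΔG denotes a destabilizing mutation,
`sign_convention` flips the classification rule, and every CLI output
header states the convention in force.

## Evaluation protocol

Pearson's product-moment r (undefined for constant input, by error);
"standard error" σ is the sample SD of residuals (pred − obs), n−1
denominator — the convention of the stability-prediction literature, stated
in every report header. Outlier-removal evaluation discards the
floor(0.1·n) points with the largest absolute residual (ties stable by
input order; a `round` mode exists) and reports metrics before and after.
The position-level splitter groups rows by (structure, chain, position) so
no mutated position appears on both sides of a train/test split; evaluation
against a bundle warns when the test table shares positions with the
bundle's training set.

## Synthetic data: what it emulates and what it does not

The toy-structure generator builds peptide backbones (N, CA, C, O, CB) with
ideal bond geometry and canonical dihedrals (helix −57°/−47°, strand
−120°/130°, or half/half), placing CB from the local backbone frame, with
optional seeded coordinate jitter (0.1 Å in the training panel). The
training-set generator samples mutations across a 6-structure panel and
constructs ground-truth ΔΔG from the package's own features:

* `two_source` (default benchmark): ΔΔG = z_sig + z_sub + ε with
  ε ~ N(0, 0.5 kcal/mol). z_sub is a standardised RSA-gated raw score,
  raw·(1 + 2·[rsa ≥ 0.3]) — visible only to the substitution branch. z_sig
  is a standardised combination of two signature components **with its
  linear RSA projection removed**: environment density inherently tracks
  burial, so without the residualisation the RSA-aware branch would see
  both sources and the two-source design would collapse. The noise level
  makes each source explain roughly half the explainable variance, with
  signal-to-noise in the range of experimental ΔΔG data.
* `linear`: a single affine function of the raw score, exactly
  representable by every pipeline stage — the noiseless recovery check.

Passing tests on these data show that the machinery recovers signal it is
able to represent, that the protocol counts are exact, and that the
consensus exploits complementary components; they say nothing about
accuracy on real mutations, which depends on real substitution tables and
training data. The benchmark uses n = 400 mutations with a 30%
position-level blind split and fixed signature-component hyperparameters
(C = 10, γ = 0.01, ε = 0.1) with the standard CV grid for the consensus
stage; at these sizes a benchmark run takes seconds and the consensus beats
the better component in ≥ 9 of 10 seeds.

## Numerical choices and degenerate inputs

Distance-to-shell assignment uses `ceil((d − d_min)/step)` with a 1e−9
guard so exact multiples land on their own cutoff; empty atom lists yield
all-zero signatures. Constant-target training data produce constant
predictors (single-leaf tree; SVR within its ε tube). Zero-variance inputs
to Pearson r raise rather than return NaN. The fold seed, stacking seed and
generator seeds are all explicit; repeated runs with the same inputs are
bit-identical, and fixture generation is byte-identical per seed.

## Known limitations

* The demonstration substitution table is synthetic; scores are internally
  consistent but not transferable to real proteins without a real table.
* The mutant structure is a truncation placeholder, not a modelled rotamer.
* 3-state secondary structure and a heavy-atom H-bond criterion are coarse
  stand-ins for DSSP-grade assignments and full H-bond energetics.
* The environment alphabet (3 × 3) is far coarser than the finer alphabets
  used by mature statistical-potential methods.
* Numerical SASA carries ~0.5% quadrature noise at the default density;
  exact arc-integration (Lee–Richards) is not implemented.
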