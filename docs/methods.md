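# Methods

## Scope and model

`graphfun` predicts residue-level binding propensities and protein-level
labels from 3D structure.  The model is a stack of message-passing layers on
a residue radius graph.  Inputs are per-residue feature vectors
(language-model embeddings, relative solvent accessibility, secondary
structure, geometric descriptors) and per-edge geometric descriptors; all
geometry enters through SE(3)-invariant quantities so that the network's
output depends on conformation, not on the coordinate frame.

### Radius graph

Nodes are residues with complete N/CA/C backbones.  A directed edge pair
(j→i, i→j) exists when the Cα–Cα distance is strictly below the cutoff
(default 15 Å; a pair at exactly the cutoff is excluded).  Edges are ordered
by (target, source) so downstream code is deterministic.  Neighbour lists
are found with a k-d tree and verified against a brute-force O(n²) oracle in
the tests; no cap is applied to neighbour counts.  The self term of the
attention ("N(i) ∪ i") is handled inside the network layer rather than as a
graph self-loop, keeping the topology clean.

### Local frames and geometric features

Each residue's frame has its origin at Cα and a Gram–Schmidt basis: e1 along
Cα→C, e3 = e1 × (N−Cα) normalised, e2 = e3 × e1.  Any fixed convention works
as long as it is used consistently; this one is documented so tests can be
exact.  Near-collinear backbones (triangle area ≤ 1e-6 Å²) raise an error
naming the residue.

The atom vocabulary is fixed to {N, CA, C, O, SC}, where SC is the heavy-atom
sidechain centroid (Cα for glycine).  Fixing the vocabulary bounds feature
dimensionality; the centroid participates in every distance/direction
calculation as a regular atom.  Node features (191 dims): 10 intra-residue
atom-pair distances × 16 RBF components; unit directions of N, C, O, SC to Cα
in the local frame (12); sin/cos of φ, ψ, ω and the three backbone bond
angles, each with a validity flag (18); an O-presence flag.  Edge features
(419 dims): 25 cross-residue atom-pair distances × 16 RBF; unit directions of
the source residue's five atoms to the target Cα in the target frame (15);
the relative rotation between the two frames as a scalar-first unit
quaternion with the scalar forced non-negative to resolve the double cover
(4).  Distances are encoded by Gaussian radial basis functions with 16
centres evenly spaced on [0, 20] Å and width equal to the spacing — wide
enough to cover the 15 Å graph cutoff plus intra-residue geometry; all RBF
parameters are configurable.  Missing O atoms zero-fill their entries and
clear the flag; chain-terminal torsions are encoded as (0, 0) with a 0
validity flag rather than dropping residues, so the node count always equals
the sequence length.

Dihedrals use the standard right-handed convention (cis = 0°), cross-checked
in the tests against an independent constructive-rotation oracle and against
`biotite`'s implementation.  Mirror reflection flips torsion signs — a
deliberate non-invariance that preserves chirality information.

### Non-geometric features

Embeddings are provider-agnostic: any table of per-residue rows keyed by
protein id qualifies, so a real language model can be dropped in by writing
its output to the documented TSV.  The bundled stub provider hashes
(id, position) into a seed and emits standard-normal rows — deterministic,
id-keyed, and extension-stable.  Embeddings are min-max normalised per
protein and per dimension (zero-range dimensions map to 0); a corpus-wide
normalisation would need training-set statistics that a single-protein
pipeline does not have, so per-protein is the default and the choice is
isolated in one function.

RSA is Shrake–Rupley accessible surface area (via `biotite`, probe 1.4 Å,
960 sphere points by default) divided by the residue's theoretical maximum
(Tien et al. 2013 scale), clipped to [0, 1]; unknown residue types fall back
to a generic 200 Å² maximum with a warning.  When a DSSP output file is
supplied, its ACC column and 8-state assignment are parsed instead — that is
the faithful path; the internal fallback exists so the package has no hard
dependency on the DSSP executable.  The fallback secondary structure is a
φ/ψ torsion-bin heuristic (helical basin → H, extended basin → E, else
coil) mapped into the 8-state vocabulary, with an explicit "unknown" state
for termini.  Both paths produce identically shaped profiles.

### Network

Hidden states are initialised by linear projections of the node and edge
features (edge features are projected too, for shape consistency with the
per-layer W_E term).  One layer performs: scaled-dot attention over
N(i) ∪ {i} with the edge feature added to the key; a residual
attention-weighted node update; a residual two-layer MLP edge update on
(ĥ_j ‖ e_ji ‖ ĥ_i); and a global-node update in which the mean of a learned
projection of the node states produces a sigmoid-gated additive correction
shared by all nodes (switchable off for ablation).  The j = i self term uses
W_K h_i and W_V h_i only: no self-edge exists, so e_ii is taken as the zero
vector — the minimal reading consistent with the update equations.
Attention is single-head; the softmax dimension d equals the hidden width.
The MLP and gate nonlinearity defaults to exact GELU (tanh and sigmoid are
available in config).  Defaults are 4 layers × 128 hidden; the scaled-down
configurations used in tests are stated with each test.

Residue heads are per-task linear+sigmoid maps of the final node states,
with output columns in a documented ligand order (DNA, RNA, peptide,
protein, ATP, HEM, ZN, CA, MG, MN, then any extra task names
alphabetically).  The protein head pools node states by a learned softmax
attention scalar before its linear+sigmoid outputs; zeroing the attention
weights recovers mean pooling exactly, which the tests exploit.

The network and its training run on a small reverse-mode automatic
differentiation engine written in NumPy (`graphfun.autodiff`): broadcast
arithmetic, matmul, row gather / segment scatter-sum, concatenation,
reductions, and smooth nonlinearities, verified against central finite
differences.  Zero-initialising all non-projection weights reduces the trunk
to the identity on the projected inputs (every update is residual), enabling
exact tests of the layer algebra.

### Training

The loss is mean binary cross-entropy over unmasked (residue, task) and
(protein, label) entries; the mask value −1 marks unannotated entries, so
multi-task batches mix proteins with different annotation coverage and a
fully masked task never changes the loss.  Optimisation is Adam (β = 0.9,
0.999) on whole-protein batches (graphs are ragged; the batch gradient is
the mean of per-protein losses).  Cross-validation is group-aware: all
variants sharing a group id — in particular the native structure and its
"predicted" counterpart used for augmentation — land in the same fold, so
augmentation cannot leak across the split.  Model selection keeps the
parameters of the epoch with the best validation loss, with early stopping
after a configurable patience.  Everything is seeded (initialisation, fold
assignment, batch order); two runs with the same seed produce bit-identical
weights.  Ensembles hold one member per fold (CV mode) or per seed (seed
mode) and predictions are the arithmetic mean of member sigmoid outputs.
No class re-weighting is applied by default.

### Evaluation and post-processing

Thresholded metrics come from the confusion table at a configurable cutoff;
undefined ratios (e.g. precision with no positive predictions) are reported
as NaN plus an entry in the report's `undefined` set, never silently as
zero.  AUC is the tie-corrected Mann–Whitney statistic and AUPR the
precision–recall step integral (scikit-learn implementations, cross-checked
in the tests against exhaustive threshold enumeration to 1e-12).  Fmax
follows the CAFA convention on a 0.00–1.00 grid in 0.01 steps: precision
averaged over proteins with at least one prediction ≥ t, recall over all
annotated proteins.  Multi-label Jaccard defines empty-vs-empty as 1.

Label diffusion is a single convex step
y′ = λ·y + (1−λ)·Σ_h w_h·label_h with bitscore-normalised weights over a
query's homology hits (self-hits ignored; queries without usable hits pass
through).  The original formulation iterates; the iteration count is a
config parameter with default 1, since one step already captures the
homology prior and keeps the update idempotent for testing.

## Synthetic data

The generator emulates the structural properties the featurizer assumes,
not real proteins.  Backbones are grown by NERF chain extension from
canonical bond lengths/angles (N–CA 1.458, CA–C 1.525, C–N 1.329 Å; ω =
180°) with (φ, ψ) drawn per segment from the α-helical (−57, −47) or
extended (−120, +130) basin plus 8° jitter; segment lengths are 6–14
residues and the helix fraction defaults to 0.5.  Ideal helix geometry
(1.5 Å rise, ~100°/residue, 3.8 Å Cα spacing) emerges from the torsions
rather than being imposed.  Carbonyl O sits in the sp2 plane opposite the
Cα/next-N bisector; a pseudo-sidechain CB atom sits 1.5 Å along the Cα
outward normal (glycine gets none, exercising the centroid fallback).
Gaussian coordinate jitter (default sd 0.1 Å) models thermal noise; the
paired "predicted-structure" variant adds independent jitter of sd 1.0 Å to
mimic model/experiment discrepancy for the augmentation path.  Sequences
are uniform random over the 20 amino acids — composition realism is
explicitly out of scope.

Binding labels follow a ghost-ligand rule: k ghost points (default 2) are
placed 3 Å outward of anchor residues, and every residue whose Cα lies
within `ligand_radius` (default 8 Å) of a ghost point is positive (~20%
positive rate at the defaults).  By default anchors are the k most buried
residues (highest Cα contact count within 10 Å, deterministic tie-break by
index), making the labels a deterministic function of the geometry — the
property the learnability tests rely on, and a caricature of real pockets,
which are enriched in buried, locally dense regions.  A uniform-random
anchor mode is available; note that with random anchors the labels carry an
irreducible random component and no predictor can score well
(Bayes-ceiling AUC ≈ 0.6 at these settings), so that mode is for exercising
the plumbing, not for learnability checks.

What passing tests on this generator do and do not show: they demonstrate
that the pipeline is correct (featurization invariants, equation fidelity,
reproducibility) and that the geometric features carry enough signal for
the network to recover a geometry-determined labelling on held-out
structures.  They do not demonstrate transfer to real binding-site data,
which differs in sequence composition, sidechain packing, label noise and
class balance.

## Numerical choices and problem sizes

Float64 throughout; attention softmax is max-shifted per neighbourhood; BCE
clips probabilities at 1e-7.  PDB output carries the format's fixed-width
1e-3 Å precision; checkpoints round-trip exactly.  The SASA estimator
samples 960 sphere points by default (240 in the synthetic pipeline, where
RSA is a feature rather than a reported quantity); its point grid is fixed
in the global frame, so the estimate — though mathematically rotation
invariant — varies by ~1% under rotation.  The end-to-end rigidity check
therefore recomputes all geometric features after a rigid transform but
reuses the profile and embeddings, isolating the network's invariance from
sampling noise in one input scalar.

Test-suite problem sizes are chosen to exercise the claims at desk scale:
graph oracles at 200 residues, equation oracles at 3–5 nodes, invariance at
100 residues × 100 transforms, and learnability with 240 proteins of 40–80
residues (180 train / 20 validation / 40 held-out) on a 2-layer, 64-hidden
model — about two minutes of training on one CPU, reaching held-out AUC ≈
0.91 at the tested seeds.

## Known limitations

- The featurizer ignores sidechain internal geometry beyond the centroid
  (no χ angles) and all hydrogens.
- The DSSP fallback is a torsion heuristic, not a hydrogen-bond assignment;
  use real DSSP files when fidelity matters.
- Only the first model of multi-model (NMR) files is read; multi-chain
  structures require an explicit chain flag (default: first chain).
- Training is single-process NumPy: adequate for hundreds of small
  proteins, not for corpus-scale runs with 1024-dim embeddings.
- Homology diffusion trusts the supplied hit table; no search is performed
  and no GO-hierarchy consistency is enforced on predictions.
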