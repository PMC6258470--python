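# Methods

This note documents the model implemented by `rnaqa`, the numerical and
design choices made where the method description leaves room, and what the
synthetic experiments do and do not demonstrate.

## Featurization

**Local frame.** Each nucleotide defines an orthonormal right-handed frame
from four atoms: origin at C1'; `x` along the glycosidic bond
(C1'→N9 for A/G, C1'→N1 for C/U); `z` along `x × y_pre` with `y_pre`
pointing from C1' to the midpoint of O5' and C5'; `y = z × x`. A frame is
rejected as degenerate when either normalized vector has a norm below
1e-6 Å (colinear or coincident frame atoms). Nucleotides missing a frame
atom are skipped during scoring (listed in the assessment's `skipped`
field) rather than failing the structure; partial residues are common in
real files and the per-nucleotide design makes skipping well-defined.

**Environment and grid.** The environment is every atom of the structure
(including the assessed nucleotide's own atoms) whose local coordinates
satisfy the *strict* bound max(|x|,|y|,|z|) < half_width, default 16 Å.
Atoms are accumulated into a `grid_edge`³ = 32³ grid of 1 Å voxels with
half-open cells `[i − 16, i − 15)` along each axis, i.e. voxel index
`floor(c + 16)`; an atom exactly at −16.0 Å is excluded, symmetric with
+16.0. Channels accumulate occupation count, mass (Da) and partial charge
(e). The three raw channel sums therefore equal the environment's atom
count, total mass and total charge — a conservation law the tests check.
Because frames co-rotate with the structure, a global rigid motion leaves
every grid bit-identical except for atoms within float rounding of a cell
boundary.

**Atom properties.** Masses and charges come from a per-(residue, atom)
table shipped with the package, covering all heavy atoms of A/U/G/C with
AMBER-family point charges; it is a self-contained stand-in for a
force-field extraction, adequate because the network only needs channels
that are consistent between training and inference, not thermodynamically
exact. Atoms without a table entry fall back to their element mass with
charge 0 (logged). Hydrogens are dropped by default — crystal structures
lack them and decoy sources differ — re-enabled by
`assign_properties(..., heavy_atoms_only=False)`. Modified nucleotides map
to their parent base through a small alias table (e.g. PSU→U); unmapped
residues are skipped with a warning.

**Normalization.** Channel-wise min–max statistics are fitted once over
the training grids (dataset-wide, not per-sample: per-sample scaling would
destroy comparability of inputs across samples), frozen into the model
checkpoint, and applied with clamping to [0, 1] at inference. A channel
that was constant during fitting maps to 0. Labels are scaled the same way
with their own min/max.

## Labels

The unfitness score of nucleotide *i* in an assessed structure, given the
native: (1) match the nucleotide's atoms by name; (2) Kabsch-superpose the
assessed copy onto the native copy (proper rotation enforced by the
determinant correction); (3) the self term is that superposition RMSD;
(4) the surroundings are the atoms inside the *native* nucleotide's cube
(itself excluded), matched to assessed atoms by (chain, residue number,
atom name); (5) the surroundings RMSD is evaluated under the step-2
transform *without re-fitting*; (6) unfitness = surroundings + self.

Two choices here are deliberate where the method statement is ambiguous:
the superposition is fitted on the nucleotide's own atoms only, because
the score measures how poorly the nucleotide's environment fits *relative
to the nucleotide's own pose*; and surroundings membership is decided from
the native structure, so the label is a fixed function of the native
reference. A nucleotide with no matched surrounding atoms (e.g. an
isolated residue) gets an undefined label and is excluded from training
sets. The label is zero for a native against itself and invariant under
rigid motion of either structure (checked to 1e-9/1e-8 Å).

Global structure RMSD is the all-matched-heavy-atom RMSD after one optimal
superposition of the full structures.

## Network and training

The reference specification — conv 8@5³, conv 16@5³, maxpool 2 (window 2,
the only window consistent with the published parameter total), conv
32@3³, conv 64@3³, dense 128, linear dense 1; no padding; stride 1; ReLU —
yields exactly 4,282,801 trainable parameters with spatial trace
32→28→24→12→10→8. Weights are Glorot-uniform from a seed, biases zero.
Training minimizes MSE with plain mini-batch gradient descent (momentum
exposed as a config, default 0), batch 128, inverted dropout 0.2 after the
activations of conv2, conv4 and the hidden dense layer. The learning rate
starts at 0.05 and is halved whenever the best validation MSE has not
strictly improved for five consecutive epochs (the patience counter resets
after each halving); training stops when the rate reaches
initial_lr × 0.5⁵ = 0.0015625, or at a max-epoch guard (default 500).
Training-history MSE is evaluated at epoch end in inference mode (dropout
off), so the recorded loss is a clean measure rather than a dropout-noised
running average.

The conv layers are executed by numba-compiled direct (shift-and-add)
kernels — forward, weight gradient, and input gradient — with a pure-numpy
im2col formulation retained as a fallback; the two paths are cross-checked
in the tests and the backward pass is verified against central finite
differences to float64 accuracy. The input gradient of the first layer is
skipped during training (nothing consumes it) and re-enabled for saliency.
Activations flow in float32 by default; `build_model(..., dtype=...)`
selects float64 where exactness matters.

### Desk-scale configuration

Hand-rolled CPU convolutions are orders of magnitude slower than the GPU
stacks the reference architecture assumes, so the end-to-end synthetic
experiments use `ModelSpec.desk_scale()` — the same layer topology with
filters (2, 2, 4, 4), all-3³ kernels and a 16-unit dense layer (≈65k
parameters) — and `TrainingSchedule.desk_scale()` (initial rate 0.01,
momentum 0.9, 150-epoch cap). Two deviations from the reference training
configuration, and why: at 0.05 this narrow network collapses to the mean
predictor (training MSE equals the label variance), and dropout 0.2 on a
2-filter layer removes half the representation at a time — crippling for
an experiment whose purpose is deliberate overfitting — so the desk spec
carries no dropout. The reference `ModelSpec()`/`TrainingSchedule()`
defaults keep the published values throughout.

## Synthetic data

`make_toy_rna` builds a single-stranded parametric helix (defaults: rise
2.8 Å, twist 33°, radius 9 Å, alternating A/U/G/C) whose nucleotides carry
C1', O5', C5', the glycosidic nitrogen, a phosphate (except the 5'
terminus), the ribose oxygens/carbons and two base-ring atoms at fixed
offsets chosen so every frame construction is well-conditioned. `perturb`
displaces every atom independently with isotropic Gaussian noise of width
σ per coordinate; for the 181-atom 14-mer the resulting structure RMSD
concentrates near √3·σ (≈1.7 Å at σ = 1, band [1.5, 1.9] over seeds, the
superposition shrinkage being only 6 degrees of freedom against 543
coordinates). `make_training_set` yields one (raw grid, raw label) sample
per frame-ready nucleotide per decoy, deterministically under a seed.

The default experiment — 14-mer, 5 decoys at each σ ∈ {0.1, 0.5, 1.0} Å,
210 samples — trains the desk-scale model below MSE 0.01 on the
normalized labels, places ≥90% of training predictions within ±0.15 of
their labels, and ranks the native helix below σ = 1.0 Å decoys in 50/50
replicates (~6 minutes on one CPU core).

What this shows: the full pipeline (frames → grids → RMSD labels →
training → scoring) is internally consistent, learnable, and
discriminative on controlled deformations. What it does not show: transfer
to real RNA. Gaussian decoys have no base pairing, sterics, torsional
chemistry or correlated backbone motion, the toy helix is not A-form
accurate, and a model with 65k parameters trained on 210 samples from one
topology says nothing about benchmark performance on crystallographic
decoy sets — reproducing those requires the original decoy archives and
trained weights, which are out of scope here.

## Evaluation metrics

The Enrichment Score of a decoy set takes the k = floor(0.1 N) records of
lowest score and of lowest RMSD (ties at the decile boundary broken by
decoy id, for determinism) and reports |E ∩ R| / (0.01 N): 10 for perfect
rank agreement, hypergeometric expectation (k²/N)/(0.01 N) = 1 for
independent scores, < 1 for anti-correlation. N ≥ 10 is enforced so the
decile is nonempty. Native identification counts a target only when the
native's score is a *strict* minimum; a tie with the best decoy is
reported but not counted. Label–prediction agreement uses the Pearson
product–moment coefficient (scipy), with degenerate zero-variance input
rejected.

## Saliency

Saliency maps are the exact gradient of the scalar output with respect to
every input voxel, computed by the network's own backward pass with
dropout inactive — raw signed values, no magnitude post-processing, since
the sign is the information (for a near-native input, negative gradients
mark score-lowering voxels). Each environment atom receives the gradient
of the voxel containing it; atoms sharing a voxel share the attribution;
atoms outside the cube receive none.

Gradient correctness is verified against central finite differences
(h = 1e-3) on *dense random* grids in float64, the standard protocol for
gradient checking: on real hard-binned grids, empty voxels are exactly 0
and zero-initialized biases put pre-activations exactly at the ReLU kink,
where the network is not differentiable and a finite difference does not
estimate the gradient. On dense inputs the analytic and numeric gradients
agree to ~1e-9 relative.

## Known limitations

- PDB is the only input dialect (no mmCIF); atom matching is by name and
  residue number, with no sequence alignment or symmetry-corrected RMSD.
- The shipped charge table is an AMBER-style default, not a force-field
  extraction; absolute charge-channel values differ from the original
  training inputs.
- No pre-trained weights are distributed; scoring real structures
  requires training on decoys of the user's own making.
- The global score sums *normalized* per-nucleotide scores;
  `invert_label_normalization` maps scores back to the Å-scale labels
  when absolute units are wanted.
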