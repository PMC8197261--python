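# Methods

## Model

`molpath` estimates a scalar molecular property from a heavy-atom graph
with three parallel feature-extraction paths, each a stack of T graph
convolution layers over per-atom feature vectors H ∈ R^{N×M}:

* **Node path.** Pair features P_ij = σ(W_np (H_i ‖ H_j) + B_np) are
  summed over the neighbourhood N(i) (which includes i itself):
  H_i ← σ(Σ_{j∈N(i)} W_n P_ij + B_n).  σ is the rectified linear unit
  throughout, ‖ is concatenation.
* **Edge path.**  The five bond channels (self, single, double, triple,
  aromatic) are stored as binary adjacency matrices A_b; a 1×1
  convolution across the channels yields scalar edge parameters
  E_ij = Σ_b w_b A_b[i,j] + c.  E_ij scales the pair pre-activation:
  P_ij = σ(E_ij · W_ep (H_i ‖ H_j) + B_ep), followed by the same
  neighbourhood update.  In *fixed* mode w = (1, 2, 3, 4, 5), c = 0 and
  both are excluded from training; in *learned* mode they are trainable,
  warm-started at 0.1 × the categorical values.
* **3-D path.**  Relative coordinates R(k)_ij = C_ik − C_jk (k ∈ x, y, z)
  scale the pair pre-activation: P_ij = σ(Σ_k R(k)_ij · W_tp (H_i ‖ H_j)
  + B_tp).  An intermediate feature Q_i = σ(Σ_{j∈N(i)} W_tq P_ij + B_tq)
  accumulates the pairs; because R_ii = 0 the self pair contributes only
  σ(B_tp), so the layer output recombines the atom's own feature:
  H_i ← σ(W_t (H_i ‖ Q_i)).  The *no-self* ablation instead uses
  H_i ← σ(W_ns Q_i) with a separate square matrix W_ns (allocating a
  distinct matrix avoids overloading W_tq, which already has its own role
  in the same forward pass).

Per-path features are merged per atom by an attention aggregator:
scores e_i^p = W_att (σ(H_i^init W_init) ‖ σ(H_i^p W_p)) with W_att ∈
R^{1×2M} so each score is scalar, α_i = softmax over the enabled paths,
and H_i = σ(W_agg Σ_p α_i^p H_i^p).  Concatenation, summation and
elementwise-maximum aggregators are available as alternatives.  With a
single enabled path the aggregator is an identity pass-through and
allocates no parameters.  Atom features are summed per dimension into one
molecular vector and an affine head produces the prediction;
classification applies a logistic at inference.

By default each path evolves its own stream for all T layers and
aggregation happens once before the readout (`aggregate_placement=
"final"`); this is what the two-stage training procedure requires, since
each path must be runnable without the aggregator.  A per-layer variant
(`"every_layer"`) replaces the shared stream with the aggregated feature
after every layer.

Relative coordinates are differences, so the 3-D path is exactly
invariant to translating the conformer (up to floating-point rounding of
the subtraction) and deliberately *not* invariant to rotation; the test
suite asserts both.  Sum readout makes predictions invariant to atom
reindexing.

## Featurization

Initial atom features are 60-dimensional binary vectors: one-hot blocks
for element (42 supported symbols: H, B, C, N, O, F, Si, P, S, Cl, Br, I,
then 30 further common elements in atomic-number order), heavy-atom
degree (0–5), hydrogen count (0–4), formal charge (−2..+2), plus aromatic
and in-ring flags.  Hydrogens are implicit (heavy-atom graph).  Aromatic
ring bonds map to the aromatic channel rather than alternating
single/double.  Unsupported elements raise an error instead of falling
into an "other" bucket, so a dataset either featurizes cleanly or fails
loudly.  Conformers for SMILES input come from a seeded single-conformer
distance-geometry embedding; molecules that fail to embed fall back to a
flat 2-D layout at z = 0 with a warning.  SDF input uses the coordinates
as written.

## Training

Two stages.  Stage 1 trains each enabled path independently against the
target, each with a temporary sum-readout + affine head; stage 2 discards
the temporary heads, freezes every path parameter (asserted bitwise
unchanged after the run), and trains the aggregator and final head.  Both
stages minimize mean squared error on minibatches of 16 (the incomplete
final minibatch is used), monitor validation loss, and stop when ten
successive epochs each improve the running best by less than 1e-4 — or at
the epoch budget.  When training ends, parameters are restored to the
epoch with the best monitored loss; without this, a transient spike early
in stage 2 can trip the patience rule while the loss is still recovering,
and the run would end on the recovery slope rather than at its best
point.

The optimizer is Adam at learning rate 3e-3 (exposed in `TrainConfig`,
with plain SGD as an alternative).  The rate was chosen for the epoch
budgets this package targets (tens of epochs per stage): at 1e-3 the
models are still far from converged within those budgets, while 3e-3
trains stably across all three paths.  Regression targets are z-scored
with training-split statistics and predictions are de-standardized at
evaluation (toggleable); classification trains with MSE on {0,1} targets
by default, with binary cross-entropy as an option, and thresholds the
logistic output at 0.5 for the confusion-matrix metrics.

Evaluation follows an 8:1:1 random split into train/validation/test
(sizes ⌊0.8n⌋, ⌊0.1n⌋, remainder), repeated over independent trials —
fresh split, fresh model, trial-shifted seeds — with metrics averaged
across trials (standard deviations reported alongside).  Regression is
scored by MAE; classification by accuracy, recall, precision, F1 (ratios
with zero denominators are reported as 0 and flagged) and trapezoidal
AUC over the ROC curve.

All numerics are float64 numpy; a small reverse-mode autodiff tape
(`molpath._tensor`) provides exact gradients, verified against central
finite differences to a relative error of 1e-4 on the full model.
Seeded runs are bitwise reproducible on one machine.

## Synthetic data

The generator (`molpath.synthetic`) draws connected random graphs: a
random-attachment tree with node degrees capped at 5 (the featurization's
degree block covers 0–5), one optional ring-closing edge (probability
0.3), elements drawn from {C: 0.5, N: 0.2, O: 0.2, S: 0.1}, bond types
from {single: 0.6, double: 0.2, triple: 0.1, aromatic: 0.1}, and Gaussian
3-D coordinates rescaled to unit mean bond length.  Chemical validity is
deliberately not enforced — the model consumes graphs, not molecules, and
unconstrained graphs keep the ground truth exact.

Four target rules with exactly known ground truth, each designed to be
informative for one configuration:

* **composition** — Σ over atoms of (C: 1, N: 2, O: 3, S: 4, others 0.5);
  learnable from node identities alone.
* **bondtype** — 1·#single + 3·#double + 5·#triple + 2·#aromatic;
  invisible to a model that ignores bond labels.  The generator can emit
  matched graph pairs differing only in one bond's label, which provably
  fool the node path (identical outputs) but not the edge path.
* **geometry** — mean pairwise Euclidean distance; requires coordinates.
* **mixed** — composition + bondtype, for multi-path experiments.

Observations add Gaussian noise (default sd 0.1).  What these fixtures do
*not* emulate: chemically consistent valences, realistic conformer
geometry, target distributions of laboratory datasets, or any correlation
structure between composition, connectivity and geometry.  Passing the
benchmarks therefore demonstrates that each path extracts the structural
signal it was designed for — not that the model reaches any particular
accuracy on real chemistry.

## Benchmarks and problem sizes

`molpath.benchmarks` runs the path-specificity experiments at fixed
desk-scale conditions: 500 molecules (8:1:1 → 400 train / 50 validation /
50 test), noise 0.1, three seeded trials per comparison, and a 40-epoch
budget per training stage under the early-stopping rule.  The four
experiments: node path vs a constant-mean baseline on composition;
learned vs fixed edge parameters on bondtype; 3-D path with vs without
the self node on geometry; node+edge (attention) vs each single path on
the mixed task.  `scripts/acceptance.py` reruns all of them from scratch
plus the equation-oracle, attention-normalization and gradient checks.

Two of the comparisons are structurally tight at these scales, and their
margins should be read accordingly:

* On the geometry task the self node is nearly irrelevant — mean pairwise
  distance does not depend on atom identity — so the with-self and
  no-self variants land within a few percent of each other and the margin
  is seed-dependent, unlike property targets where dropping the atom's
  own feature would be costly.
* On the mixed task the edge path sees everything the node path sees plus
  the bond labels, so the node+edge model's ceiling is roughly parity
  with the edge-only model: it beats node-only decisively, while the
  node+edge vs edge-only margin is a few percent and seed-dependent.

## Known limitations

* Kernel sizes above 1 for the edge-parameter convolution are not
  supported; distance-based 3-D features are not implemented.
* No stereochemistry, protonation states, multi-conformer handling, or
  charges beyond ±2.
* Single-output heads only; no multitask regression.
* CPU-only, one molecule per forward pass; fine for the graph sizes the
  package targets, not for high-throughput screening.
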