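# molpath

Multi-path graph convolutional networks for molecular property
estimation, for researchers who want a transparent, fully inspectable
reference implementation of multi-structure feature extraction on
molecular graphs — with an exact synthetic test bed instead of an opaque
benchmark dependency.

## The model

A molecule is a heavy-atom graph: element symbols, typed bonds stored as
five binary adjacency channels (self, single, double, triple, aromatic),
optional 3-D coordinates, and a 60-dimensional one-hot feature vector per
atom.  Three parallel **feature-extraction paths** update per-atom
features H ∈ R^{N×M} (σ is the rectified linear unit, ‖ concatenation,
N(i) the neighbourhood of atom i including i itself):

* **node path** — pair features P_ij = σ(W_np (H_i ‖ H_j) + B_np),
  update H_i ← σ(Σ_{j∈N(i)} W_n P_ij + B_n);
* **edge path** — scalar edge parameters E_ij = Σ_b w_b A_b[i,j] + c
  (a 1×1 convolution over the five bond channels; learnable, or fixed to
  the categorical values 1..5) scale the pair pre-activation:
  P_ij = σ(E_ij · W_ep (H_i ‖ H_j) + B_ep);
* **3-D path** — relative coordinates R(k)_ij = C_ik − C_jk scale the
  pairs, Q_i accumulates them, and the atom's own feature is recombined:
  H_i ← σ(W_t (H_i ‖ Q_i)) (or σ(W_ns Q_i) in the no-self ablation).

A per-atom **attention** over the paths (α_i = softmax of scalar scores
e_i^p = W_att (σ(H_i^init W_init) ‖ σ(H_i^p W_p))) merges the streams,
H_i = σ(W_agg Σ_p α_i^p H_i^p); concat/sum/max aggregators are
alternatives.  Summing atom features per dimension gives the molecular
vector, and an affine head predicts the property.  Training is
**two-stage**: each path first learns alone with a temporary head, then
the paths are frozen and the aggregator + final head are trained (Adam,
minibatches of 16, early stopping when ten successive epochs improve the
validation loss by less than 1e-4).  Protocols, metrics (MAE;
accuracy/recall/precision/F1 and ROC/AUC) and the 8:1:1 multi-trial
evaluation are in `molpath.training` / `molpath.evaluation`.

See `docs/methods.md` for assumptions, parameter defaults, and what the
synthetic benchmarks do and do not show.

## Worked example

Generate a synthetic dataset whose target is a weighted bond-type count
(1·single + 3·double + 5·triple + 2·aromatic, plus noise), train an
edge-path model, and compare against predicting the training mean:

```python
import numpy as np
from molpath import *
from molpath.synthetic import SynthSpec, make_dataset
from molpath.training import TrainConfig, SplitSpec, split_dataset, train_model

spec = SynthSpec(n_molecules=200, mode="bondtype", noise_sd=0.1, seed=7)
records = [(r.graph, r.target) for r in make_dataset(spec)]
train, valid, test = split_dataset(records, SplitSpec(base_seed=7), trial=0)

model = build_model(ModelConfig(paths=("edge",), edge_mode="learned", seed=7))
print(count_parameters(model), parameter_report(model))
logs = train_model(model, train, valid, TrainConfig(max_epochs=30, seed=7))
print(evaluate_model(model, test).metrics)
```

Output:

```
21913 {'edge': 21852, 'aggregator': 0, 'head': 61}
{'mae': 2.0960499981911697}
```

The model has 21,913 scalar parameters (two edge layers of
60-dimensional weights plus the affine head; a single-path model
allocates no aggregator).  After two-stage training its test MAE is 2.10
versus 4.76 for the constant-mean baseline on the same split: the edge
path has learned most of the bond-type signal from 160 training
molecules.  Real datasets load the same way through
`read_csv_dataset("data.csv", smiles_col=..., target_col=...)` (SMILES,
with optional seeded conformer embedding for the 3-D path) or
`read_sdf_dataset` (V2000 SDF with coordinates).

The same flows are available from the shell:

```sh
molpath synth --mode bondtype -n 500 --noise 0.1 --seed 1 --out data.sdf
molpath train --data data.sdf --paths node,edge --agg attention --seed 1 --out run/
molpath evaluate --checkpoint run/checkpoint.npz --data data.sdf --attention-csv alpha.csv
molpath predict --checkpoint run/checkpoint.npz --smiles "CCO"
```

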