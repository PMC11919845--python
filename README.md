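# dtiblocks

Drug–target interaction (DTI) prediction with stacked, gated graph-neural
blocks — for computational chemists and method developers who need a
virtual-screening-style predictor that runs, trains and explains itself
entirely on CPU with no deep-learning framework dependency.

## The model

A drug is a molecular graph G = (V, E) over heavy atoms with 64-dim
indicator features x_i (element, formal charge, degree, aromaticity, ring
membership). The drug encoder stacks *GNN blocks*: units of N
message-passing layers

    x_i' = σ( F1(x_i) + F2( Σ_{j∈N(i)} x_j ) )

(attention-weighted aggregation in the GAT variant). Each block widens its
last layer to 2C channels and refines the expansion with a gated linear
unit plus residual,

    h(L+1) = h_{n−1}(L+1) + GLU(h_n(L+1)) · d ,

and the block output is filtered against its input by GRU-style gates
(reset R, update Z, weights shared across blocks):

    out = (1 − Z) ⊙ h(L) + Z ⊙ tanh( h(L+1) W1h + R ⊙ (h(L) W2h) + bh ).

A per-channel max over atoms reads out the embedding. A protein is encoded
twice — a multi-scale 1-D CNN (windows 3/5/7) over 30-dim residue
embeddings, and a 3-layer weighted GCN over the contact-map graph with
neighbour scaling M_ij/√(deg_i·deg_j) — then fused per residue as
(L2(T_seq·Ws) + L2(T_graph·Wg))·Wt and max-pooled. Concatenated embeddings
feed a 3-layer MLP trained with binary cross-entropy.

Also included: random / unseen-entity / similarity-cluster dataset splits
(Tanimoto–ECFP4 for drugs, alignment identity for proteins), screening
metrics (AUROC, AUPR, enrichment factor, ROC enrichment), per-block feature
diversity DS_G (an over-smoothing diagnostic) and gradient-weighted
per-atom attribution maps. A synthetic-benchmark generator plants a
learnable motif-AND rule so the whole pipeline is testable offline; see
`docs/methods.md` for the science and the design choices.

The neural encoders run on a small NumPy reverse-mode autodiff core that
ships with the package (`dtiblocks.autodiff`) — no PyTorch/TensorFlow
required.

## Worked example

```python
from dtiblocks import (SyntheticSpec, generate_dataset, DTIModel,
                       DrugEncoderConfig, TargetEncoderConfig, TrainConfig)
from dtiblocks.splits_metrics import SplitSpec, split_pairs

dataset, drugs, targets = generate_dataset(SyntheticSpec(seed=1))
tr, va, te = split_pairs(dataset.pairs, SplitSpec(seed=1))
model = DTIModel(dataset, DrugEncoderConfig(channels=64, n_blocks=2),
                 TargetEncoderConfig(channels=64))
res = model.fit(tr, va, TrainConfig(seed=1, max_epochs=8, patience=8))
print(res.summary())
print(res.evaluate(te).as_dict())
```

prints

```
DTI model fit summary
====================================================
pairs: 1000  drugs: 300  targets: 100
drug encoder: 2 blocks x 2 layers (gat_gcn), C=64, d=1.0
target encoder: windows (3, 5, 7), 3 WGCN layers, graph=on
parameters: 340471
epochs run: 8  best epoch: 3  best val AUROC: 1.0000
final train loss: 0.0086
{'auroc': 1.0, 'aupr': 1.0, 'acc': 0.8, 'precision': 0.712, 'recall': 1.0, 'f1': 0.832}
```

The benchmark plants a conjunction rule — a pair interacts iff the drug
carries a carboxylic-acid group AND the target carries a 5-residue motif —
so a correctly wired model should separate the classes essentially
perfectly (AUROC/AUPR 1.0 here), while threshold-at-0.5 metrics (acc,
precision) reflect the model's calibration rather than its ranking.

The same pipeline is available from the shell:

```bash
dtiblocks simulate --out-dir data/ --seed 1
dtiblocks split --pairs data/pairs.tsv --strategy cluster_drug \
    --smiles data/drugs.tsv --seed 1 --out-prefix splits/
dtiblocks train --pairs splits/train.tsv --val-pairs splits/val.tsv \
    --smiles data/drugs.tsv --fasta data/targets.fasta \
    --contacts data/contacts --out model.npz --seed 1
dtiblocks rank --model model.npz --query-target T0003 \
    --library data/drugs.tsv --smiles data/drugs.tsv \
    --fasta data/targets.fasta --contacts data/contacts \
    --pairs data/pairs.tsv --out ranking.tsv
```

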