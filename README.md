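# heterodualnet

Drug repositioning — finding new therapeutic indications for approved
drugs — can be framed as link prediction on a bipartite drug–disease
graph. `heterodualnet` predicts unknown drug–disease associations with a
dual-branch convolutional neural network whose input for a candidate
pair (drug *r<sub>i</sub>*, disease *d<sub>k</sub>*) is a small
heterogeneous matrix assembled from similarity and association data.

## The model

Inputs are four intra-drug similarity matrices *R₁..R₄*, an intra-disease
similarity matrix *D* (taken as given), and a binary association matrix
*A* (1 = known treatment association, 0 = unknown):

* *R₁, R₂, R₃* — cosine similarity between the drugs' binary feature
  vectors (chemical substructures, target-protein domains,
  target-protein annotations):
  *R_t(i,j) = f_{t,i}·f_{t,j} / (‖f_{t,i}‖‖f_{t,j}‖)*.
* *R₄* — drug-related disease correlation: with *DI_m*, *DI_n* the
  disease sets of drugs *i*, *j*,
  *R₄(i,j) = [Σ_{k∈DI_m} max_{d∈DI_n} D(k,d) + Σ_{k∈DI_n} max_{d∈DI_m} D(k,d)] / (|DI_m|+|DI_n|)*.

For each pair, two 5 × (N<sup>DR</sup>+N<sup>DI</sup>) embeddings are
built: the **hetero-layer** *X_L* stacks rows
[*R_t(i,·)* | *A(i,·)*] for *t* = 1..4 over [*Aᵀ(·,k)* | *D(k,·)*];
the **neighbour hetero-layer** *X_{L−N}* is built the same way from each
entity's single most similar neighbour per similarity view. Each layer
feeds one branch of the network (conv 3×5 → 1×2 max-pool → conv 3×5 →
1×2 max-pool → dense softmax head); the two score pairs are fused
convexly, *h = α·h_L + (1−α)·h_R*, and trained with the weighted squared
error *α‖h_L−y‖² + (1−α)‖h_R−y‖²*.

Evaluation follows the protocol the model was designed for: balanced
undersampling (all positives plus an equal number of sampled unknown
pairs), five-fold cross-validation with per-fold recomputation of *R₄*
from a test-masked association matrix (so a test pair's label never
enters its own input), per-drug ROC AUC averaged over drugs, PR AUC, and
top-*k* recall.

## Worked example

```python
import numpy as np
import heterodualnet as hdn

# planted-cluster synthetic dataset: 60 drugs, 40 diseases, 3 matched clusters
bundle, truth = hdn.generate_bundle(hdn.SyntheticSpec())
print(bundle.associations.values.sum())   # 460 known associations

# recover 20% held-out positives
auc = hdn.evaluation.holdout_recovery(bundle, hdn.ModelConfig(), fraction=0.2, seed=1)
print(round(auc, 3))                      # 0.857
```

The printed AUC is the pooled ROC AUC for ranking the 92 hidden
positives against five times as many unseen unknown pairs after
training on the remaining data — well above the ≈0.5 obtained when
training labels are permuted, showing the model recovers the planted
cluster signal rather than memorising labels.

The same pipeline is available from the shell:

```sh
heterodualnet --out-dir data simulate          # write a synthetic dataset
heterodualnet --out-dir out similarities data  # compute R1..R4
heterodualnet --out-dir out --seed 1 cv data   # cross-validated metrics
heterodualnet --out-dir out --seed 1 train data
heterodualnet --out-dir out rank data drug007 --model-path out/model.npz
```

`cv` prints macro/micro ROC AUC, macro/micro PR AUC and recall at
k = 30…240 and writes them to `cv_report.tsv`.

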