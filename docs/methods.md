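# Methods

## Problem and model

Known drug–disease treatment associations are sparse: in the reference
dataset scale the package is built around (763 drugs × 681 diseases),
only 3051 of 519 603 pairs are known, and the remaining 516 552 are
unlabelled candidates, not confirmed negatives. The predictor scores a
candidate pair by convolving two small heterogeneous matrices that place
the pair in its similarity context.

For pair (drug *i*, disease *k*), the original hetero-layer *X_L* is a
5 × (N_drugs + N_diseases) matrix: rows 1–4 are the drug's rows from the
four intra-drug similarity views concatenated with its association row;
row 5 is the disease's association column (transposed) concatenated with
its disease-similarity row. The neighbour hetero-layer *X_{L−N}*
replaces each entity by its single most similar neighbour per view
(argmax excluding self, ties to the smallest index), encoding the
premise that similar drugs treat related diseases. Each layer drives one
branch of a dual CNN; branch score pairs are fused convexly with weight
α and trained with the weighted squared error of both branches against
the one-hot label.

Two readings of the neighbour layer's right block are possible: the
drug neighbours' own association rows (the propagation reading) or the
disease neighbour's row repeated. The drug-rows reading is the default
(`neighbor_right_block="drug_rows"`); the literal alternative is kept as
a config switch for comparison, though it indexes association rows by a
disease index and is only well-defined when that index is in range.

## Parameters

| parameter | default | meaning |
|---|---|---|
| N1, N2 | 3, 6 | filters in conv layers 1 and 2 |
| conv shapes | 3×5, 3×5 | filter height × width (odd, same-padded, stride 1) |
| pool shapes | 1×2, 1×2 | max-pool window = stride; width halves per layer |
| α | 0.5 | fusion weight on the original-layer branch |
| dropout | 0.5 | applied to the flattened features during training |
| optimizer | Adam, lr 1e-3 | batch size 32, at most 100 epochs |
| early stop | patience 5, tol 1e-4 | stop when mean epoch loss plateaus |

The conv/pool geometry follows the reference architecture's illustrated
values, which are the only ones stated; α, the optimizer, learning rate,
batch size, epochs, dropout rate and the He-scaled normal initialization
are this package's own choices (nothing upstream specifies them) and are
all exposed in `ModelConfig`. α = 0.5 is the symmetric prior over the
two branches. The loss is squared error on softmax outputs — the
model's stated objective — although cross-entropy would be the
conventional choice for a classifier head.

The network is implemented directly in numpy with analytic gradients
(the model is ~10⁴ parameters; no framework is needed). Gradient
correctness is enforced by a finite-difference check at 1e-4 relative
tolerance in the test suite and the acceptance script.

## Evaluation protocol

Balanced undersampling assigns all positives plus an equal number of
uniformly sampled unknown pairs to subset A; every remaining unknown
pair forms subset B. Five-fold cross-validation splits subset A; each
round trains on four parts and scores the fifth together with all of
subset B. Before each round, the fold's test positives are zeroed out of
the association matrix and the disease-correlation similarity R4 *and*
all embeddings are rebuilt from that masked copy — both read the
association matrix, so masking only R4 would still leak a test pair's
label into its own input. The headline ROC AUC is the mean of per-drug
AUCs over drugs with at least one test positive (drugs with none are
excluded and counted); pooled micro AUCs and a per-drug macro PR AUC are
reported as secondary, since the averaging convention for PR is not
fixed upstream. ROC AUC uses the Mann–Whitney convention (ties half
credit); PR AUC is interpolation-free step integration. Top-k recall is
the per-drug fraction of test positives ranked in the top k candidates,
averaged over drugs, at k = 30…240 by default.

## Synthetic data

The generator plants matched clusters: drugs and diseases are
partitioned into `n_clusters` groups, drug cluster *c* is preferentially
associated with disease cluster *c* (cell probability 0.5 inside matched
blocks, 0.02 outside), each feature type gives each cluster a disjoint
block of characteristic features (on-probability 0.6 inside the cluster,
background 0.05), and the disease similarity is two-level (0.8 within,
0.1 between, unit diagonal). Defaults are 60 drugs, 40 diseases, 3
clusters, 200 features per type — large enough that within-cluster
cosine and disease-correlation similarities clearly exceed
between-cluster values, small enough that a full five-seed recovery
benchmark runs in minutes on one CPU. The disease similarity is
generated directly as block structure rather than from simulated
ontologies: it is an input to the method, and only its geometry matters.

What the generator does not emulate: realistic feature marginals (real
chemical-fingerprint bits are far sparser and correlated), heavy-tailed
per-drug association counts, or ontology-derived disease similarity
structure. Passing the recovery benchmark therefore shows the pipeline
extracts planted similarity/association signal without leakage — not
that it attains any particular accuracy on real pharmacological data.

## Numerical choices and degenerate inputs

* Cosine similarity with an all-zero feature vector is 0 off-diagonal
  (no evidence), 1 on the diagonal.
* R4 between drugs where either disease set is empty is 0; the shared
  denominator makes R4 symmetric by construction, which is asserted.
* Similarity inputs asymmetric by more than 1e-8 are rejected; smaller
  asymmetry is averaged away, and the diagonal is forced to exactly 1.
* Neighbour selection excludes self (the unit diagonal would always
  win); a drug or disease whose off-diagonal similarities are all zero
  falls back to itself and the neighbour set is flagged degenerate.
* Odd widths before a pool are zero-padded by one column; activations
  are post-ReLU, so padding never exceeds a real activation.
* Argmax ties (neighbour selection, pooling) break to the lowest index;
  candidate-ranking ties break by disease identifier. All randomness
  (sampling, fold assignment, initialization, dropout, shuffling) flows
  from explicit seeds, and identical seeds give identical plans, weights
  and loss curves.

## Benchmark sizes

The recovery benchmark holds out 20% of positives, trains on the
remainder plus an equal negative sample, and ranks the held-out
positives against 5× as many unseen unknown pairs; it is averaged over
five seeds, with a permuted-label control expected near AUC 0.5. The
fold-planner arithmetic is checked at the full reference scale
(763 × 681), which costs only memory for index arrays.

## Known limitations

* Real-data reproduction requires the original similarity/association
  matrices as TSV inputs; the package ships none and headline numbers on
  that dataset are not asserted anywhere.
* Exactly one neighbour per similarity view is used, as designed; there
  is no k-neighbour aggregation.
* The squared-error objective can saturate more easily than
  cross-entropy; training on hard real-world instances may need more
  epochs than the synthetic defaults.
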