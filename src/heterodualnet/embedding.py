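"""Heterogeneous pair-embedding matrices.

For a candidate pair (drug r_i, disease d_k) the model input is a
5 x (N_drugs + N_diseases) matrix that stacks, row-wise:

    rows 1-4 : [ R_t(i, .) | A(i, .) ]   for the four drug-similarity views
    row 5    : [ A(., k)^T | D(k, .) ]

(the "hetero-layer", original variant).  The second branch uses the
"neighbour" variant built the same way from each entity's single most
similar neighbour per view: drug neighbours m, n, p, q (argmax of
R1..R4 excluding self) and disease neighbour l (argmax of D excluding
self):

    rows 1-4 : [ R1(m, .) | A(m, .) ], ..., [ R4(q, .) | A(q, .) ]
    row 5    : [ A(., l)^T | D(l, .) ]

The right block of the neighbour variant admits a second convention in
which the disease-neighbour association row A(l, .) is repeated four
times; ``neighbor_right_block="disease_row"`` selects it.  The default
``"drug_rows"`` uses the drug neighbours' own association rows, which is
what the propagation premise (similar drugs treat related diseases)
implies.

All entries are similarities or binary associations, hence in [0, 1].
Embeddings are built on demand (per pair or per batch); the full
N_drugs x N_diseases collection is never materialized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .data_io import AssociationMatrix, SimilarityMatrix

Variant = Literal["original", "neighbor"]
RightBlock = Literal["drug_rows", "disease_row"]


@dataclass
class PairEmbedding:
    drug_index: int
    disease_index: int
    variant: Variant
    values: np.ndarray  # (5, n_drugs + n_diseases)


@dataclass(frozen=True)
class NeighborSet:
    """Most-similar neighbours of a (drug, disease) pair, one per view."""

    m: int  # argmax of R1(i, .) excluding i
    n: int  # argmax of R2(i, .) excluding i
    p: int  # argmax of R3(i, .) excluding i
    q: int  # argmax of R4(i, .) excluding i
    l: int  # argmax of D(k, .) excluding k
    degenerate: bool = False  # some view had no informative neighbour

    @property
    def drug_neighbors(self) -> tuple[int, int, int, int]:
        return (self.m, self.n, self.p, self.q)


def _as_array(x) -> np.ndarray:
    return x.values if hasattr(x, "values") else np.asarray(x, dtype=float)


def _nearest_excluding_self(sim: np.ndarray, index: int) -> tuple[int, bool]:
    """Argmax of row `index` with the diagonal excluded.

    Ties break to the smallest index.  If every off-diagonal entry is 0
    there is no informative neighbour and the entity is its own fallback.
    """
    row = sim[index].copy()
    row[index] = -np.inf
    if np.max(row) <= 0.0:
        return index, True
    return int(np.argmax(row)), False


def select_neighbors(i: int, k: int, R: Sequence[SimilarityMatrix],
                     D: SimilarityMatrix) -> NeighborSet:
    """Find the most similar drug per similarity view and disease in D."""
    picks, degenerate = [], False
    for Rt in R:
        j, fell_back = _nearest_excluding_self(_as_array(Rt), i)
        degenerate |= fell_back
        picks.append(j)
    l, fell_back = _nearest_excluding_self(_as_array(D), k)
    degenerate |= fell_back
    return NeighborSet(*picks, l=l, degenerate=degenerate)


def build_hetero_matrix(i: int, k: int, R: Sequence[SimilarityMatrix],
                        A: AssociationMatrix,
                        D: SimilarityMatrix) -> PairEmbedding:
    """Original hetero-layer X_L for pair (drug i, disease k)."""
    Av = _as_array(A)
    Dv = _as_array(D)
    n_drugs, n_dis = Av.shape
    if not (0 <= i < n_drugs and 0 <= k < n_dis):
        raise IndexError(f"pair ({i}, {k}) outside {n_drugs} x {n_dis} grid")
    X = np.empty((5, n_drugs + n_dis))
    for t, Rt in enumerate(R):
        X[t, :n_drugs] = _as_array(Rt)[i]
        X[t, n_drugs:] = Av[i]
    X[4, :n_drugs] = Av[:, k]
    X[4, n_drugs:] = Dv[k]
    return PairEmbedding(i, k, "original", X)


def build_neighbor_hetero_matrix(
    i: int, k: int, neighbors: NeighborSet, R: Sequence[SimilarityMatrix],
    A: AssociationMatrix, D: SimilarityMatrix,
    right_block: RightBlock = "drug_rows",
) -> PairEmbedding:
    """Neighbour hetero-layer X_{L-N} for pair (drug i, disease k)."""
    Av = _as_array(A)
    Dv = _as_array(D)
    n_drugs, n_dis = Av.shape
    if not (0 <= i < n_drugs and 0 <= k < n_dis):
        raise IndexError(f"pair ({i}, {k}) outside {n_drugs} x {n_dis} grid")
    X = np.empty((5, n_drugs + n_dis))
    for t, (Rt, j) in enumerate(zip(R, neighbors.drug_neighbors)):
        X[t, :n_drugs] = _as_array(Rt)[j]
        X[t, n_drugs:] = (Av[j] if right_block == "drug_rows"
                          else Av[neighbors.l])
    X[4, :n_drugs] = Av[:, neighbors.l]
    X[4, n_drugs:] = Dv[neighbors.l]
    out = PairEmbedding(i, k, "neighbor", X)
    return out


class EmbeddingContext:
    """Precomputed neighbour tables plus fast batched embedding assembly.

    Neighbour choices depend only on the similarity matrices, so they are
    computed once per context (one context per cross-validation fold, since
    R4 and A change with the fold mask).
    """

    def __init__(self, R: Sequence[SimilarityMatrix], A: AssociationMatrix,
                 D: SimilarityMatrix,
                 right_block: RightBlock = "drug_rows") -> None:
        self.R = [_as_array(Rt) for Rt in R]
        self.A = _as_array(A)
        self.D = _as_array(D)
        self.right_block = right_block
        self.n_drugs, self.n_diseases = self.A.shape
        self.width = self.n_drugs + self.n_diseases
        # neighbour of every drug in each view, and of every disease in D
        self.drug_nbr = np.empty((4, self.n_drugs), dtype=int)
        self.degenerate_drugs: set[int] = set()
        for t, Rt in enumerate(self.R):
            for i in range(self.n_drugs):
                j, fb = _nearest_excluding_self(Rt, i)
                self.drug_nbr[t, i] = j
                if fb:
                    self.degenerate_drugs.add(i)
        self.disease_nbr = np.empty(self.n_diseases, dtype=int)
        self.degenerate_diseases: set[int] = set()
        for k in range(self.n_diseases):
            self.disease_nbr[k], fb = _nearest_excluding_self(self.D, k)
            if fb:
                self.degenerate_diseases.add(k)

    def neighbors(self, i: int, k: int) -> NeighborSet:
        return NeighborSet(
            *(int(self.drug_nbr[t, i]) for t in range(4)),
            l=int(self.disease_nbr[k]),
            degenerate=(i in self.degenerate_drugs
                        or k in self.degenerate_diseases),
        )

    def build_batch(self, drugs: np.ndarray, diseases: np.ndarray,
                    variant: Variant) -> np.ndarray:
        """Assemble embeddings for index arrays -> (batch, 5, width)."""
        drugs = np.asarray(drugs, dtype=int)
        diseases = np.asarray(diseases, dtype=int)
        B = drugs.size
        nd = self.n_drugs
        X = np.empty((B, 5, self.width))
        if variant == "original":
            rows = [drugs] * 4
            dis_row = diseases
            right_rows = [drugs] * 4
        else:
            rows = [self.drug_nbr[t][drugs] for t in range(4)]
            dis_row = self.disease_nbr[diseases]
            right_rows = (rows if self.right_block == "drug_rows"
                          else [dis_row] * 4)
        for t in range(4):
            X[:, t, :nd] = self.R[t][rows[t]]
            X[:, t, nd:] = self.A[right_rows[t]]
        X[:, 4, :nd] = self.A[:, dis_row].T
        X[:, 4, nd:] = self.D[dis_row]
        return X
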