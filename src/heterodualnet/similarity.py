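"""Intra-drug similarity matrices.

Four drug x drug similarity views feed the embedding:

* R1, R2, R3 — cosine similarity between binary feature vectors of one
  evidence type each (chemical substructures, target-protein domains,
  target-protein annotations):

      R_t(i, j) = f_{t,i} . f_{t,j} / (||f_{t,i}|| ||f_{t,j}||)

* R4 — drug-related disease correlation.  With DI_m the diseases known
  for drug i and DI_n those for drug j,

      R4(i, j) = [ sum_{k in DI_m} max_{d in DI_n} D(k, d)
                 + sum_{k in DI_n} max_{d in DI_m} D(k, d) ]
                 / (|DI_m| + |DI_n|)

  i.e. the average of best-match disease similarities in both directions.

R4 depends on the association matrix, so during cross-validation it must
be recomputed from a copy of A in which the held-out positives are zeroed
(`mask_associations`) — otherwise a test pair's own label leaks into its
input representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import AssociationMatrix, DrugFeatureTable, SimilarityMatrix


@dataclass(frozen=True)
class DiseaseNeighborhood:
    """The diseases known to be associated with one drug."""

    drug_index: int
    disease_indices: frozenset[int]

    @property
    def count(self) -> int:
        return len(self.disease_indices)


def disease_neighborhood(A: AssociationMatrix | np.ndarray,
                         drug_index: int) -> DiseaseNeighborhood:
    values = A.values if isinstance(A, AssociationMatrix) else np.asarray(A)
    return DiseaseNeighborhood(
        drug_index, frozenset(np.flatnonzero(values[drug_index]).tolist())
    )


def cosine_similarity(F: DrugFeatureTable) -> SimilarityMatrix:
    """Cosine similarity between the drugs' binary feature vectors.

    A drug with an all-zero feature vector has similarity 0 to every other
    drug (no evidence) and 1 to itself.
    """
    X = F.values.astype(float)  # (n_features, n_drugs)
    dots = X.T @ X
    norms = np.sqrt(np.diag(dots))
    denom = np.outer(norms, norms)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, dots / np.where(denom > 0, denom, 1.0), 0.0)
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(list(F.drug_ids), sim)


def disease_correlation_similarity(A: AssociationMatrix,
                                   D: SimilarityMatrix) -> SimilarityMatrix:
    """Drug similarity from best-match correlation of their disease sets.

    Drugs whose disease neighbourhood is empty get similarity 0 to every
    other drug.  The result is symmetric by construction of the shared
    denominator; this is asserted, not enforced.
    """
    if list(A.disease_ids) != list(D.entity_ids):
        raise ValueError("association columns and disease-similarity ids "
                         "must be aligned before computing R4")
    Av = A.values.astype(float)  # (n_drugs, n_diseases)
    Dv = D.values
    n_drugs, n_dis = Av.shape
    counts = Av.sum(axis=1)  # |DI| per drug

    # C[j, k] = max_{d in DI_j} D(k, d): best match of disease k against
    # drug j's disease set (0 when the set is empty).
    C = np.zeros((n_drugs, n_dis))
    for j in range(n_drugs):
        idx = np.flatnonzero(Av[j])
        if idx.size:
            C[j] = Dv[:, idx].max(axis=1)

    # directional[i, j] = sum_{k in DI_i} C[j, k]
    directional = Av @ C.T
    numer = directional + directional.T
    denom = counts[:, None] + counts[None, :]
    both_nonempty = (counts[:, None] > 0) & (counts[None, :] > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(both_nonempty, numer / np.where(denom > 0, denom, 1.0),
                       0.0)
    assert np.allclose(sim, sim.T, atol=1e-10)
    sim = np.clip(sim, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(list(A.drug_ids), sim)


def mask_associations(A: AssociationMatrix,
                      pairs) -> AssociationMatrix:
    """Return a copy of A with each (drug_index, disease_index) pair zeroed.

    Used to hide test-fold positives from R4 recomputation and from the
    embedding inputs during cross-validation.
    """
    values = A.values.copy()
    for i, k in pairs:
        if not (0 <= i < A.n_drugs and 0 <= k < A.n_diseases):
            raise IndexError(f"pair ({i}, {k}) outside "
                             f"{A.n_drugs} x {A.n_diseases} matrix")
        values[i, k] = 0
    return AssociationMatrix(list(A.drug_ids), list(A.disease_ids), values)


def feature_similarities(features) -> list[SimilarityMatrix]:
    """Cosine similarities for the three feature tables, in order."""
    return [cosine_similarity(F) for F in features]
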