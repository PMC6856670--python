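"""Typed matrix containers and tab-delimited I/O.

All matrices travel as TSV files with a header row of column identifiers
and a first column of row identifiers.  Three container types cover the
inputs of the pipeline:

* :class:`DrugFeatureTable` — binary features x drugs table for one
  evidence type (chemical substructures, target-protein domains,
  target-protein annotations);
* :class:`SimilarityMatrix` — square symmetric matrix in [0, 1] with unit
  diagonal, over drugs or over diseases;
* :class:`AssociationMatrix` — binary drugs x diseases matrix, 1 = known
  treatment association, 0 = unknown.

`align_dataset` restricts every matrix to the common drug and disease
identifier sets so that row/column index ``i`` means the same entity
everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

FeatureType = Literal["chemical", "domain", "annotation"]

#: tolerance under which asymmetric similarity input is silently averaged
SYMMETRY_TOL = 1e-8


class ValidationError(ValueError):
    """An input matrix violates a container invariant."""


class ParseError(ValueError):
    """A cell of an input file could not be parsed as a number."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(x for x in ids if x in seen or seen.add(x))
        raise ValidationError(f"duplicate {what} identifier: {dup!r}")
    return ids


def _first_offending_cell(mask: np.ndarray, rows, cols) -> str:
    r, c = np.argwhere(mask)[0]
    return f"row {rows[r]!r}, column {cols[c]!r}"


def _check_binary(values: np.ndarray, rows, cols, what: str) -> np.ndarray:
    bad = ~np.isin(values, (0.0, 1.0))
    if bad.any():
        raise ValidationError(
            f"non-binary entry in {what} at "
            f"{_first_offending_cell(bad, rows, cols)}: "
            f"{values[bad][0]!r}"
        )
    return values.astype(np.int8)


@dataclass
class DrugFeatureTable:
    """Binary feature presence table for one drug evidence type."""

    feature_type: FeatureType
    feature_ids: list[str]
    drug_ids: list[str]
    values: np.ndarray  # (n_features, n_drugs), int {0,1}

    def __post_init__(self) -> None:
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.feature_ids), len(self.drug_ids)):
            raise ValidationError(
                f"feature table shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.drug_ids)} drugs"
            )
        self.values = _check_binary(
            self.values.astype(float), self.feature_ids, self.drug_ids,
            f"{self.feature_type} feature table",
        )

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    def restrict_drugs(self, drug_ids: Sequence[str]) -> "DrugFeatureTable":
        idx = [self.drug_ids.index(d) for d in drug_ids]
        return DrugFeatureTable(
            self.feature_type, list(self.feature_ids), list(drug_ids),
            self.values[:, idx],
        )


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0, 1] with unit diagonal."""

    entity_ids: list[str]
    values: np.ndarray  # (n, n), float

    def __post_init__(self) -> None:
        self.entity_ids = _check_unique(self.entity_ids, "entity")
        v = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if v.shape != (n, n):
            raise ValidationError(
                f"similarity matrix shape {v.shape} is not ({n}, {n})"
            )
        asym = np.abs(v - v.T)
        if asym.max(initial=0.0) > SYMMETRY_TOL:
            raise ValidationError(
                "asymmetric similarity matrix at "
                f"{_first_offending_cell(asym > SYMMETRY_TOL, self.entity_ids, self.entity_ids)}"
            )
        v = (v + v.T) / 2.0  # average away round-off within tolerance
        out = (v < -1e-12) | (v > 1 + 1e-12)
        if out.any():
            raise ValidationError(
                "similarity value outside [0, 1] at "
                f"{_first_offending_cell(out, self.entity_ids, self.entity_ids)}: "
                f"{v[out][0]!r}"
            )
        np.fill_diagonal(v, 1.0)  # self-similarity is 1 by construction
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def n(self) -> int:
        return len(self.entity_ids)

    def restrict(self, ids: Sequence[str]) -> "SimilarityMatrix":
        idx = [self.entity_ids.index(e) for e in ids]
        return SimilarityMatrix(list(ids), self.values[np.ix_(idx, idx)])


@dataclass
class AssociationMatrix:
    """Binary drug x disease association matrix (1 = known, 0 = unknown)."""

    drug_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray  # (n_drugs, n_diseases), int {0,1}

    def __post_init__(self) -> None:
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        v = np.asarray(self.values)
        if v.shape != (len(self.drug_ids), len(self.disease_ids)):
            raise ValidationError(
                f"association matrix shape {v.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.disease_ids)} diseases"
            )
        self.values = _check_binary(
            v.astype(float), self.drug_ids, self.disease_ids,
            "association matrix",
        )

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    def restrict(self, drug_ids: Sequence[str],
                 disease_ids: Sequence[str]) -> "AssociationMatrix":
        ri = [self.drug_ids.index(d) for d in drug_ids]
        ci = [self.disease_ids.index(d) for d in disease_ids]
        return AssociationMatrix(
            list(drug_ids), list(disease_ids), self.values[np.ix_(ri, ci)]
        )


@dataclass
class ScoreTable:
    """Prediction records: (drug_id, disease_id, score, known_label)."""

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["drug_id", "disease_id", "score", "known_label"]
        )
    )

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records,
                          columns=["drug_id", "disease_id", "score",
                                   "known_label"])
        scores = df["score"].to_numpy(dtype=float) if len(df) else np.empty(0)
        if len(scores) and ((scores < 0) | (scores > 1)).any():
            bad = scores[(scores < 0) | (scores > 1)][0]
            raise ValidationError(f"score outside [0, 1]: {bad!r}")
        df["known_label"] = df["known_label"].astype(str)
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class DatasetBundle:
    """All inputs restricted to common drug and disease orderings."""

    features: tuple[DrugFeatureTable, DrugFeatureTable, DrugFeatureTable]
    disease_sim: SimilarityMatrix
    associations: AssociationMatrix
    n_drugs_dropped: int = 0
    n_diseases_dropped: int = 0

    @property
    def drug_ids(self) -> list[str]:
        return self.associations.drug_ids

    @property
    def disease_ids(self) -> list[str]:
        return self.associations.disease_ids


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    body = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            body[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ParseError(
                f"{path.name}: non-numeric cell at row {bad.index[0]!r}, "
                f"column {col!r}: {bad.iloc[0]!r}"
            ) from None
    return body


def load_matrix(path: str | Path, kind: str,
                feature_type: FeatureType = "chemical"):
    """Load a typed matrix from a header-ed TSV file.

    Parameters
    ----------
    path : file path
    kind : one of ``"feature"``, ``"similarity"``, ``"association"``
    feature_type : evidence type attached when ``kind == "feature"``
    """
    df = _read_tsv(path)
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    v = df.to_numpy(dtype=float)
    if kind == "feature":
        return DrugFeatureTable(feature_type, rows, cols, v)
    if kind == "similarity":
        return SimilarityMatrix(rows, v)
    if kind == "association":
        return AssociationMatrix(rows, cols, v)
    raise ValueError(f"unknown matrix kind: {kind!r}")


def write_matrix(obj, path: str | Path) -> None:
    """Write any of the three container types back to headered TSV."""
    if isinstance(obj, DrugFeatureTable):
        df = pd.DataFrame(obj.values, index=obj.feature_ids,
                          columns=obj.drug_ids)
    elif isinstance(obj, SimilarityMatrix):
        df = pd.DataFrame(obj.values, index=obj.entity_ids,
                          columns=obj.entity_ids)
    elif isinstance(obj, AssociationMatrix):
        df = pd.DataFrame(obj.values, index=obj.drug_ids,
                          columns=obj.disease_ids)
    else:  # pragma: no cover
        raise TypeError(f"cannot write {type(obj).__name__}")
    df.to_csv(path, sep="\t", float_format="%.12g")


def align_dataset(f1: DrugFeatureTable, f2: DrugFeatureTable,
                  f3: DrugFeatureTable, disease_sim: SimilarityMatrix,
                  associations: AssociationMatrix) -> DatasetBundle:
    """Restrict all matrices to shared drug and disease identifiers.

    Drug order follows the association matrix's rows filtered to the ids
    present in every feature table; disease order follows its columns
    filtered to the disease-similarity ids.
    """
    drug_sets = [set(f.drug_ids) for f in (f1, f2, f3)]
    common_drugs = [d for d in associations.drug_ids
                    if all(d in s for s in drug_sets)]
    common_dis = [d for d in associations.disease_ids
                  if d in set(disease_sim.entity_ids)]
    if not common_drugs:
        raise ValidationError("no drug identifiers shared by all inputs")
    if not common_dis:
        raise ValidationError("no disease identifiers shared by all inputs")
    return DatasetBundle(
        features=(
            f1.restrict_drugs(common_drugs),
            f2.restrict_drugs(common_drugs),
            f3.restrict_drugs(common_drugs),
        ),
        disease_sim=disease_sim.restrict(common_dis),
        associations=associations.restrict(common_drugs, common_dis),
        n_drugs_dropped=len(associations.drug_ids) - len(common_drugs),
        n_diseases_dropped=len(associations.disease_ids) - len(common_dis),
    )


def write_scores(scores: ScoreTable, path: str | Path) -> None:
    """Write a score table as TSV with >= 6 significant digits."""
    df = scores.records.copy()
    df["score"] = [format(float(s), ".9g") for s in df["score"]]
    df.to_csv(path, sep="\t", index=False)


def load_scores(path: str | Path) -> ScoreTable:
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str,
                                            "disease_id": str,
                                            "known_label": str})
    return ScoreTable(df)
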