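"""Evaluation protocol: undersampled folds, cross-validation, metrics.

Known-association pairs (label 1) are vastly outnumbered by unknown
pairs, so training uses balanced undersampling: subset A holds all
positives plus an equal number of uniformly sampled unknown pairs;
subset B holds every remaining unknown pair.  Five-fold cross-validation
splits subset A; in each round four parts train the model and the fifth,
together with all of subset B, is scored.

Leakage control: before training a fold, its test positives are zeroed
out of the association matrix; the disease-correlation similarity R4 and
every embedding are rebuilt from that masked copy, so a test pair's own
label never appears in its input.

The headline metric is the macro (per-drug average) ROC AUC; pooled
(micro) ROC and PR AUCs are reported as secondary.  Top-k recall is the
fraction of a drug's test positives ranked within its k highest-scored
candidates, averaged over evaluated drugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_io import AssociationMatrix, DatasetBundle, ScoreTable
from .dualcnn import HeteroDualNet, ModelConfig, TrainingSet, train
from .embedding import EmbeddingContext
from .similarity import (disease_correlation_similarity, feature_similarities,
                         mask_associations)

DEFAULT_KS = tuple(range(30, 241, 30))

#: a scorer maps (drug_indices, disease_indices) -> scores; used to inject
#: reference scorers into the harness in place of a trained model
Scorer = Callable[[np.ndarray, np.ndarray], np.ndarray]


class UndefinedMetricError(ValueError):
    """The metric is undefined for the given labels (single class)."""


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney; ties get half credit)."""
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise UndefinedMetricError("ROC AUC needs both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve, step integration."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise UndefinedMetricError("PR AUC needs at least one positive")
    return float(average_precision_score(labels,
                                         np.asarray(scores, dtype=float)))


def recall_at_k(ranked_labels: Sequence[Sequence[int]], k: int) -> float:
    """Mean fraction of each drug's positives within its top-k ranking.

    ``ranked_labels`` holds, per evaluated drug, the binary labels of its
    candidates already sorted by score descending.  Drugs without any
    positive are excluded from the average.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    fractions = []
    for labels in ranked_labels:
        labels = np.asarray(labels)
        total = labels.sum()
        if total == 0:
            continue
        fractions.append(labels[:k].sum() / total)
    if not fractions:
        raise UndefinedMetricError("no drug has a positive to recall")
    return float(np.mean(fractions))


# ---------------------------------------------------------------------------
# fold planning
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Balanced undersampled pair sets and their fold assignment.

    subset A = all positives + equally many sampled unknown pairs, split
    into ``n_folds`` near-equal parts; subset B = remaining unknown pairs.
    """

    pos_pairs: np.ndarray   # (P, 2) drug, disease indices
    neg_pairs: np.ndarray   # (P, 2)
    pos_fold: np.ndarray    # (P,) in [0, n_folds)
    neg_fold: np.ndarray    # (P,)
    subset_b: np.ndarray    # (M, 2)
    n_folds: int
    seed: int

    @property
    def n_positives(self) -> int:
        return len(self.pos_pairs)

    @property
    def n_unknown_pairs(self) -> int:
        """Size of the unknown-pair universe (sampled + subset B)."""
        return len(self.neg_pairs) + len(self.subset_b)

    def train_test_split(self, fold: int):
        """(train_pairs, train_labels, test_pairs, test_labels) for a fold;
        test covers the held-out part of subset A only (B is appended by
        the harness)."""
        tr_p = self.pos_pairs[self.pos_fold != fold]
        tr_n = self.neg_pairs[self.neg_fold != fold]
        te_p = self.pos_pairs[self.pos_fold == fold]
        te_n = self.neg_pairs[self.neg_fold == fold]
        train_pairs = np.vstack([tr_p, tr_n])
        train_labels = np.r_[np.ones(len(tr_p), int), np.zeros(len(tr_n), int)]
        test_pairs = np.vstack([te_p, te_n])
        test_labels = np.r_[np.ones(len(te_p), int), np.zeros(len(te_n), int)]
        return train_pairs, train_labels, test_pairs, test_labels


def make_fold_plan(A: AssociationMatrix, n_folds: int = 5,
                   seed: int = 0) -> FoldPlan:
    """Draw the balanced undersample and assign cross-validation folds."""
    if n_folds < 2:
        raise ValueError(f"n_folds must be >= 2, got {n_folds}")
    values = A.values
    pos_flat = np.flatnonzero(values.ravel() == 1)
    neg_flat = np.flatnonzero(values.ravel() == 0)
    P = pos_flat.size
    if P < n_folds:
        raise ValueError(f"need at least {n_folds} positives, got {P}")
    if P > neg_flat.size:
        raise ValueError("more positives than unknown pairs; cannot "
                         "undersample a balanced negative set")
    rng = np.random.default_rng(seed)
    sampled = rng.choice(neg_flat, size=P, replace=False)
    in_sample = np.zeros(values.size, dtype=bool)
    in_sample[sampled] = True
    rest = neg_flat[~in_sample[neg_flat]]

    def unravel(flat: np.ndarray) -> np.ndarray:
        return np.column_stack(np.unravel_index(flat, values.shape))

    def fold_assign(n: int) -> np.ndarray:
        f = np.tile(np.arange(n_folds), -(-n // n_folds))[:n]
        rng.shuffle(f)
        return f

    return FoldPlan(
        pos_pairs=unravel(pos_flat), neg_pairs=unravel(np.sort(sampled)),
        pos_fold=fold_assign(P), neg_fold=fold_assign(P),
        subset_b=unravel(rest), n_folds=n_folds, seed=seed,
    )


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------

@dataclass
class FoldDiagnostics:
    fold: int
    n_train: int
    n_test: int
    n_drugs_evaluated: int
    n_drugs_skipped: int
    final_train_loss: float | None = None


@dataclass
class EvaluationReport:
    per_drug_auc: list[float]
    macro_roc_auc: float
    micro_roc_auc: float
    macro_pr_auc: float
    micro_pr_auc: float
    recall_at_k: dict[int, float]
    folds: list[FoldDiagnostics] = field(default_factory=list)
    #: averaging convention of the headline AUCs
    averaging: str = "macro (per-drug mean); micro reported as secondary"

    def summary_rows(self):
        rows = [("macro_roc_auc", self.macro_roc_auc),
                ("micro_roc_auc", self.micro_roc_auc),
                ("macro_pr_auc", self.macro_pr_auc),
                ("micro_pr_auc", self.micro_pr_auc)]
        rows += [(f"recall_at_{k}", v) for k, v in self.recall_at_k.items()]
        return rows


def run_cross_validation(bundle: DatasetBundle, config: ModelConfig,
                         plan: FoldPlan, scorer: Scorer | None = None,
                         ks: Sequence[int] = DEFAULT_KS,
                         score_subset_b: bool = True) -> EvaluationReport:
    """Run the full leakage-safe protocol and aggregate metrics.

    ``scorer`` replaces model training when given (used to validate the
    harness with reference scorers); otherwise a fresh model is trained
    per fold with the fold's seed derived from ``config.seed``.
    """
    D = bundle.disease_sim
    R123 = feature_similarities(bundle.features)
    per_drug_auc: list[float] = []
    per_drug_pr: list[float] = []
    ranked_label_lists: list[np.ndarray] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    diagnostics: list[FoldDiagnostics] = []

    for fold in range(plan.n_folds):
        tr_pairs, tr_labels, te_pairs, te_labels = plan.train_test_split(fold)
        test_pos = te_pairs[te_labels == 1]
        A_masked = mask_associations(bundle.associations,
                                     [tuple(p) for p in test_pos])
        R4 = disease_correlation_similarity(A_masked, D)
        ctx = EmbeddingContext(R123 + [R4], A_masked, D,
                               right_block=config.neighbor_right_block)
        if score_subset_b and len(plan.subset_b):
            te_pairs = np.vstack([te_pairs, plan.subset_b])
            te_labels = np.r_[te_labels, np.zeros(len(plan.subset_b), int)]
        final_loss = None
        if scorer is None:
            fold_cfg = ModelConfig(**{**config.__dict__,
                                      "seed": config.seed + fold})
            model = train(TrainingSet(ctx, tr_pairs[:, 0], tr_pairs[:, 1],
                                      tr_labels), fold_cfg)
            scores = model.score_batch(ctx, te_pairs[:, 0], te_pairs[:, 1])
            final_loss = model.loss_history[-1]
        else:
            scores = np.asarray(scorer(te_pairs[:, 0], te_pairs[:, 1]),
                                dtype=float)
        pooled_scores.append(scores)
        pooled_labels.append(te_labels)

        evaluated = skipped = 0
        drugs_with_pos = np.unique(test_pos[:, 0])
        for drug in drugs_with_pos:
            sel = te_pairs[:, 0] == drug
            d_scores, d_labels = scores[sel], te_labels[sel]
            if d_labels.min() == d_labels.max():
                skipped += 1
                continue
            per_drug_auc.append(roc_auc(d_scores, d_labels))
            per_drug_pr.append(pr_auc(d_scores, d_labels))
            order = np.argsort(-d_scores, kind="stable")
            ranked_label_lists.append(d_labels[order])
            evaluated += 1
        diagnostics.append(FoldDiagnostics(
            fold=fold, n_train=len(tr_pairs), n_test=len(te_pairs),
            n_drugs_evaluated=evaluated, n_drugs_skipped=skipped,
            final_train_loss=final_loss))

    all_scores = np.concatenate(pooled_scores)
    all_labels = np.concatenate(pooled_labels)
    return EvaluationReport(
        per_drug_auc=per_drug_auc,
        macro_roc_auc=float(np.mean(per_drug_auc)),
        micro_roc_auc=roc_auc(all_scores, all_labels),
        macro_pr_auc=float(np.mean(per_drug_pr)),
        micro_pr_auc=pr_auc(all_scores, all_labels),
        recall_at_k={k: recall_at_k(ranked_label_lists, k) for k in ks},
        folds=diagnostics,
    )


# ---------------------------------------------------------------------------
# held-out positive recovery benchmark
# ---------------------------------------------------------------------------

def holdout_recovery(bundle: DatasetBundle, config: ModelConfig,
                     fraction: float = 0.2, seed: int = 0,
                     neg_eval_ratio: int = 5,
                     permute_labels: bool = False) -> float:
    """Pooled ROC AUC for recovering a held-out fraction of positives.

    A fraction of the known associations is hidden; R4 and all
    embeddings are rebuilt from the masked matrix; a model is trained on
    the remaining positives plus an equal number of sampled unknown
    pairs; the hidden positives are then scored against
    ``neg_eval_ratio`` times as many unseen unknown pairs.

    ``permute_labels`` shuffles the training labels first — the negative
    control whose AUC should sit near chance.
    """
    from .synthetic import holdout_positives

    A = bundle.associations
    D = bundle.disease_sim
    A_train, held = holdout_positives(A, fraction, seed=seed)
    R4 = disease_correlation_similarity(A_train, D)
    ctx = EmbeddingContext(feature_similarities(bundle.features) + [R4],
                           A_train, D,
                           right_block=config.neighbor_right_block)
    rng = np.random.default_rng(seed + 1)
    pos = np.argwhere(A_train.values == 1)
    unknown_flat = np.flatnonzero(A.values.ravel() == 0)
    train_neg_flat = rng.choice(unknown_flat, size=len(pos), replace=False)
    train_neg = np.column_stack(np.unravel_index(train_neg_flat,
                                                 A.values.shape))
    pairs = np.vstack([pos, train_neg])
    labels = np.r_[np.ones(len(pos), int), np.zeros(len(train_neg), int)]
    if permute_labels:
        labels = rng.permutation(labels)
    fold_cfg = ModelConfig(**{**config.__dict__, "seed": seed})
    model = train(TrainingSet(ctx, pairs[:, 0], pairs[:, 1], labels),
                  fold_cfg)

    remaining = np.setdiff1d(unknown_flat, train_neg_flat,
                             assume_unique=False)
    n_eval_neg = min(neg_eval_ratio * len(held), remaining.size)
    eval_neg = np.column_stack(np.unravel_index(
        rng.choice(remaining, size=n_eval_neg, replace=False),
        A.values.shape))
    scores = np.r_[model.score_batch(ctx, held[:, 0], held[:, 1]),
                   model.score_batch(ctx, eval_neg[:, 0], eval_neg[:, 1])]
    truth = np.r_[np.ones(len(held), int), np.zeros(len(eval_neg), int)]
    return roc_auc(scores, truth)


# ---------------------------------------------------------------------------
# candidate ranking (case-study-style export)
# ---------------------------------------------------------------------------

def rank_candidates(model: HeteroDualNet | None, drug_id: str,
                    bundle: DatasetBundle, ctx: EmbeddingContext | None = None,
                    top_n: int | None = None,
                    scorer: Scorer | None = None) -> ScoreTable:
    """Rank a drug's unknown diseases by predicted score, descending.

    Diseases already known to be associated are excluded.  Ties break by
    disease identifier.  ``scorer`` substitutes for the model when given.
    """
    try:
        i = bundle.drug_ids.index(drug_id)
    except ValueError:
        raise KeyError(f"unknown drug id: {drug_id!r}") from None
    unknown = np.flatnonzero(bundle.associations.values[i] == 0)
    drugs = np.full(unknown.size, i)
    if scorer is not None:
        scores = np.asarray(scorer(drugs, unknown), dtype=float)
    else:
        if model is None:
            raise RuntimeError("either a trained model or a scorer is needed")
        if ctx is None:
            D = bundle.disease_sim
            A = bundle.associations
            R4 = disease_correlation_similarity(A, D)
            ctx = EmbeddingContext(feature_similarities(bundle.features)
                                   + [R4], A, D,
                                   right_block=model.config.
                                   neighbor_right_block)
        scores = model.score_batch(ctx, drugs, unknown)
    ids = np.array(bundle.disease_ids, dtype=object)[unknown]
    order = sorted(range(unknown.size), key=lambda j: (-scores[j], ids[j]))
    if top_n is not None:
        order = order[:top_n]
    import pandas as pd
    return ScoreTable(pd.DataFrame({
        "drug_id": drug_id,
        "disease_id": [ids[j] for j in order],
        "score": [scores[j] for j in order],
        "known_label": "unknown",
    }))
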