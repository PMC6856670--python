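"""Shared fixtures: small hand-sized instances and the synthetic default."""

from __future__ import annotations

import numpy as np
import pytest

import heterodualnet as hdn


@pytest.fixture(scope="session")
def toy_bundle():
    """5 drugs x 4 diseases with fully distinct, hand-checkable matrices."""
    rng = np.random.default_rng(42)
    drug_ids = [f"r{i}" for i in range(1, 6)]
    dis_ids = [f"d{k}" for k in range(1, 5)]
    feats = []
    for t, ftype in enumerate(("chemical", "domain", "annotation")):
        values = (rng.random((6, 5)) < 0.5).astype(int)
        values[:, t] = 1  # guarantee no all-zero drug column
        feats.append(hdn.DrugFeatureTable(
            ftype, [f"{ftype}{j}" for j in range(6)], drug_ids, values))
    Dv = np.round(rng.uniform(0.05, 0.95, (4, 4)), 2)
    Dv = (Dv + Dv.T) / 2
    np.fill_diagonal(Dv, 1.0)
    D = hdn.SimilarityMatrix(dis_ids, Dv)
    Av = (rng.random((5, 4)) < 0.4).astype(int)
    Av[0, 0] = 1  # at least one positive
    A = hdn.AssociationMatrix(drug_ids, dis_ids, Av)
    return hdn.DatasetBundle(features=tuple(feats), disease_sim=D,
                             associations=A)


@pytest.fixture(scope="session")
def toy_matrices(toy_bundle):
    """(R1..R4, A, D) for the toy bundle."""
    R123 = hdn.feature_similarities(toy_bundle.features)
    R4 = hdn.disease_correlation_similarity(toy_bundle.associations,
                                            toy_bundle.disease_sim)
    return R123 + [R4], toy_bundle.associations, toy_bundle.disease_sim


@pytest.fixture(scope="session")
def default_synthetic():
    """The default planted-cluster dataset (shared; treat as read-only)."""
    return hdn.generate_bundle(hdn.SyntheticSpec())


# ---------------------------------------------------------------------------
# independent oracles (loop-based, no vectorization shared with the
# implementation)
# ---------------------------------------------------------------------------

def cosine_oracle(values: np.ndarray) -> np.ndarray:
    """Double-loop cosine similarity over columns of a features x drugs
    table; zero-vector drugs get 0 off-diagonal, 1 on the diagonal."""
    n = values.shape[1]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                out[i, j] = 1.0
                continue
            a, b = values[:, i].astype(float), values[:, j].astype(float)
            na, nb = np.sqrt(a @ a), np.sqrt(b @ b)
            out[i, j] = (a @ b) / (na * nb) if na > 0 and nb > 0 else 0.0
    return out


def disease_correlation_oracle(Av: np.ndarray, Dv: np.ndarray) -> np.ndarray:
    """Brute-force enumeration of the best-match disease correlation."""
    n = Av.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            DIm = np.flatnonzero(Av[i])
            DIn = np.flatnonzero(Av[j])
            if len(DIm) == 0 or len(DIn) == 0:
                out[i, j] = 0.0
                continue
            s = sum(max(Dv[k, d] for d in DIn) for k in DIm)
            s += sum(max(Dv[k, d] for d in DIm) for k in DIn)
            out[i, j] = s / (len(DIm) + len(DIn))
    return out


def conv_relu_oracle(X: np.ndarray, W: np.ndarray,
                     b: np.ndarray) -> np.ndarray:
    """Naive same-padded stride-1 convolution + ReLU, all loops.

    X: (C, H, Wd); W: (N, C, kh, kw); b: (N,). Returns (N, H, Wd)."""
    C, H, Wd = X.shape
    N, _, kh, kw = W.shape
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    V = np.zeros((C, H + 2 * ph, Wd + 2 * pw))
    V[:, ph:ph + H, pw:pw + Wd] = X
    out = np.zeros((N, H, Wd))
    for n in range(N):
        for i in range(H):
            for j in range(Wd):
                acc = b[n]
                for c in range(C):
                    for di in range(kh):
                        for dj in range(kw):
                            acc += V[c, i + di, j + dj] * W[n, c, di, dj]
                out[n, i, j] = max(acc, 0.0)
    return out


def max_pool_oracle(S: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Naive block max with zero padding to full blocks. S: (C, H, W)."""
    ph, pw = window
    C, H, W = S.shape
    Ho, Wo = -(-H // ph), -(-W // pw)
    out = np.zeros((C, Ho, Wo))
    for c in range(C):
        for i in range(Ho):
            for j in range(Wo):
                block = [S[c, ii, jj] if ii < H and jj < W else 0.0
                         for ii in range(i * ph, (i + 1) * ph)
                         for jj in range(j * pw, (j + 1) * pw)]
                out[c, i, j] = max(block)
    return out


def branch_forward_oracle(X: np.ndarray, state, config) -> np.ndarray:
    """Straight-line branch forward (no dropout): returns the score pair."""
    S1 = conv_relu_oracle(X[None], state.W1, state.b1)
    P1 = max_pool_oracle(S1, config.pool1_shape)
    S2 = conv_relu_oracle(P1, state.W2, state.b2)
    P2 = max_pool_oracle(S2, config.pool2_shape)
    u = P2.reshape(-1)
    z = state.Wd @ u + state.bd
    e = np.exp(z - z.max())
    return e / e.sum()


def roc_auc_oracle(scores, labels) -> float:
    """All-pairs Mann-Whitney comparison with half credit for ties."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def pr_auc_oracle(scores, labels) -> float:
    """Threshold enumeration: sum precision * recall increments."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    thresholds = np.unique(scores)[::-1]
    n_pos = labels.sum()
    area, prev_recall = 0.0, 0.0
    for th in thresholds:
        pred = scores >= th
        tp = int(((labels == 1) & pred).sum())
        fp = int(((labels == 0) & pred).sum())
        precision = tp / (tp + fp) if tp + fp else 1.0
        recall = tp / n_pos
        area += precision * (recall - prev_recall)
        prev_recall = recall
    return area
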