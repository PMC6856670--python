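"""Dual-branch convolutional network over pair embeddings.

Each branch runs the same stack on its 5 x W input (W = n_drugs +
n_diseases):

    zero-pad -> conv (N1 filters, ReLU) -> max-pool (1x2, stride = window)
    -> zero-pad -> conv (N2 filters, ReLU) -> max-pool -> flatten
    -> dropout (training only) -> dense (2 units) -> softmax

The left branch reads the original hetero-layer, the right branch the
neighbour hetero-layer.  Their two-component softmax outputs h_L, h_R
(first component = probability of association) are fused convexly,

    h = alpha * h_L + (1 - alpha) * h_R,

and trained by minimizing the weighted squared error

    loss = alpha * ||h_L - y||^2 + (1 - alpha) * ||h_R - y||^2

with y = (1, 0) for associated pairs and (0, 1) otherwise.  Squared error
on softmax outputs — not cross-entropy — is deliberate: it is the model's
stated objective.

The network is small enough that forward and backward passes are written
directly in numpy; gradients are analytic and verified against finite
differences in the test suite.  Convolutions use "same" zero padding with
stride 1; pooling zero-pads odd widths so halving is exact (inputs are
post-ReLU, hence non-negative, so zero padding never wins a max
spuriously... except against an all-zero window, where it ties at 0).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .embedding import EmbeddingContext, RightBlock


class ConfigurationError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Architecture and optimisation settings.

    Defaults follow the reference architecture: 3 filters of 3x5 in the
    first convolution, 6 in the second, 1x2 max-pooling after each.
    alpha is the convex weight on the original-layer branch.
    """

    n1: int = 3
    n2: int = 6
    conv1_shape: tuple[int, int] = (3, 5)
    conv2_shape: tuple[int, int] = (3, 5)
    pool1_shape: tuple[int, int] = (1, 2)
    pool2_shape: tuple[int, int] = (1, 2)
    alpha: float = 0.5
    dropout_rate: float = 0.5
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    neighbor_right_block: RightBlock = "drug_rows"
    plateau_patience: int = 5
    plateau_tol: float = 1e-4

    def __post_init__(self) -> None:
        self.conv1_shape = tuple(self.conv1_shape)
        self.conv2_shape = tuple(self.conv2_shape)
        self.pool1_shape = tuple(self.pool1_shape)
        self.pool2_shape = tuple(self.pool2_shape)
        for name in ("conv1_shape", "conv2_shape"):
            kh, kw = getattr(self, name)
            if kh % 2 == 0 or kw % 2 == 0:
                raise ConfigurationError(
                    f"{name}={kh}x{kw}: convolution dimensions must be odd "
                    "for integral same-padding")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError(f"alpha={self.alpha} outside [0, 1]")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError(
                f"dropout_rate={self.dropout_rate} outside [0, 1)")


# ---------------------------------------------------------------------------
# primitive layers (batch, channels, height, width)
# ---------------------------------------------------------------------------

def pad_same(X: np.ndarray, kernel: tuple[int, int]) -> np.ndarray:
    """Zero-pad spatial dims so a stride-1 convolution preserves shape."""
    kh, kw = kernel
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    return np.pad(X, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


def conv_relu(X: np.ndarray, weights: np.ndarray, biases: np.ndarray,
              return_pre: bool = False):
    """Same-padded stride-1 convolution followed by ReLU.

    X : (batch, in_channels, H, W); weights : (n_filters, in_channels,
    kh, kw); biases : (n_filters,).  Output (batch, n_filters, H, W).
    """
    n_f, c_in, kh, kw = weights.shape
    if X.ndim != 4 or X.shape[1] != c_in:
        raise ConfigurationError(
            f"input with {X.shape[1] if X.ndim == 4 else '?'} channels does "
            f"not match filters expecting {c_in}")
    if kh > X.shape[2] + kh - 1 or kw > X.shape[3] + kw - 1:  # pragma: no cover
        raise ConfigurationError("filter larger than padded input")
    V = pad_same(X, (kh, kw))
    patches = np.lib.stride_tricks.sliding_window_view(V, (kh, kw),
                                                       axis=(2, 3))
    Z = np.einsum("bchwij,ncij->bnhw", patches, weights,
                  optimize=True) + biases[None, :, None, None]
    S = np.maximum(Z, 0.0)
    return (S, Z) if return_pre else S


def _conv_backward(dS: np.ndarray, Z: np.ndarray, X: np.ndarray,
                   weights: np.ndarray):
    """Gradients of conv_relu: returns (dX, dW, db)."""
    n_f, c_in, kh, kw = weights.shape
    dZ = dS * (Z > 0)
    V = pad_same(X, (kh, kw))
    patches = np.lib.stride_tricks.sliding_window_view(V, (kh, kw),
                                                       axis=(2, 3))
    dW = np.einsum("bnhw,bchwij->ncij", dZ, patches, optimize=True)
    db = dZ.sum(axis=(0, 2, 3))
    dV = np.zeros_like(V)
    H, W = X.shape[2], X.shape[3]
    for di in range(kh):
        for dj in range(kw):
            dV[:, :, di:di + H, dj:dj + W] += np.einsum(
                "bnhw,nc->bchw", dZ, weights[:, :, di, dj], optimize=True)
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    dX = dV[:, :, ph:ph + H, pw:pw + W]
    return dX, dW, db


def max_pool(S: np.ndarray, window: tuple[int, int],
              return_argmax: bool = False):
    """Non-overlapping max pooling (stride = window), zero-padded to fit."""
    ph, pw = window
    B, C, H, W = S.shape
    Hp, Wp = -(-H // ph) * ph, -(-W // pw) * pw
    Sp = np.pad(S, ((0, 0), (0, 0), (0, Hp - H), (0, Wp - W)))
    blocks = Sp.reshape(B, C, Hp // ph, ph, Wp // pw, pw)
    blocks = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(
        B, C, Hp // ph, Wp // pw, ph * pw)
    arg = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]
    if return_argmax:
        return out, (arg, (H, W), window)
    return out


def _pool_backward(dOut: np.ndarray, cache) -> np.ndarray:
    arg, (H, W), (ph, pw) = cache
    B, C, Ho, Wo = dOut.shape
    dBlocks = np.zeros((B, C, Ho, Wo, ph * pw))
    np.put_along_axis(dBlocks, arg[..., None], dOut[..., None], axis=-1)
    dSp = dBlocks.reshape(B, C, Ho, Wo, ph, pw).transpose(
        0, 1, 2, 4, 3, 5).reshape(B, C, Ho * ph, Wo * pw)
    return dSp[:, :, :H, :W]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def fuse_scores(h_left: np.ndarray, h_right: np.ndarray,
                alpha: float) -> np.ndarray:
    """Convex fusion of the two branch score pairs."""
    if not 0.0 <= alpha <= 1.0:
        raise ConfigurationError(f"alpha={alpha} outside [0, 1]")
    return alpha * np.asarray(h_left) + (1.0 - alpha) * np.asarray(h_right)


def pair_loss(h_left: np.ndarray, h_right: np.ndarray, y: np.ndarray,
              alpha: float) -> float:
    """Weighted squared error of both branch outputs against the one-hot y."""
    h_left, h_right, y = (np.asarray(a, dtype=float)
                          for a in (h_left, h_right, y))
    return float(alpha * np.sum((h_left - y) ** 2)
                 + (1.0 - alpha) * np.sum((h_right - y) ** 2))


# ---------------------------------------------------------------------------
# branch and model
# ---------------------------------------------------------------------------

@dataclass
class BranchState:
    """All learnable parameters of one branch."""

    W1: np.ndarray  # (N1, 1, kh1, kw1)
    b1: np.ndarray  # (N1,)
    W2: np.ndarray  # (N2, N1, kh2, kw2)
    b2: np.ndarray  # (N2,)
    Wd: np.ndarray  # (2, flat)
    bd: np.ndarray  # (2,)

    def params(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2,
                "b2": self.b2, "Wd": self.Wd, "bd": self.bd}


def _pooled_width(width: int, window: tuple[int, int]) -> int:
    return -(-width // window[1])


def flat_features(config: ModelConfig, width: int) -> int:
    w1 = _pooled_width(width, config.pool1_shape)
    w2 = _pooled_width(w1, config.pool2_shape)
    h = 5
    h1 = -(-h // config.pool1_shape[0])
    h2 = -(-h1 // config.pool2_shape[0])
    return config.n2 * h2 * w2


def init_branch(config: ModelConfig, width: int,
                rng: np.random.Generator) -> BranchState:
    """Small symmetric random initialization, He-scaled per layer."""
    def w(shape):
        fan_in = int(np.prod(shape[1:]))
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    kh1, kw1 = config.conv1_shape
    kh2, kw2 = config.conv2_shape
    flat = flat_features(config, width)
    return BranchState(
        W1=w((config.n1, 1, kh1, kw1)), b1=np.zeros(config.n1),
        W2=w((config.n2, config.n1, kh2, kw2)), b2=np.zeros(config.n2),
        Wd=w((2, flat)), bd=np.zeros(2),
    )


def branch_forward(X: np.ndarray, state: BranchState, config: ModelConfig,
                   training: bool = False,
                   rng: np.random.Generator | None = None,
                   cache: dict | None = None):
    """Run one branch; X is (batch, 5, width) or a single (5, width).

    Returns (u, h): the flattened feature vectors before the dense layer
    and the softmax score pairs.  With ``cache`` a dict, intermediate
    activations are stored for the backward pass.
    """
    single = X.ndim == 2
    X = X[None] if single else X
    Xc = X[:, None, :, :]  # add channel axis
    if state.Wd.shape[1] != flat_features(config, X.shape[2]):
        raise ConfigurationError(
            f"dense layer expects {state.Wd.shape[1]} features but the "
            f"configuration yields {flat_features(config, X.shape[2])}")
    S1, Z1 = conv_relu(Xc, state.W1, state.b1, return_pre=True)
    P1, pc1 = max_pool(S1, config.pool1_shape, return_argmax=True)
    S2, Z2 = conv_relu(P1, state.W2, state.b2, return_pre=True)
    P2, pc2 = max_pool(S2, config.pool2_shape, return_argmax=True)
    u = P2.reshape(P2.shape[0], -1)
    if training and config.dropout_rate > 0.0:
        if rng is None:
            raise ConfigurationError("training forward pass needs an RNG "
                                     "for dropout")
        mask = (rng.random(u.shape) >= config.dropout_rate) / (
            1.0 - config.dropout_rate)
        u_drop = u * mask
    else:
        mask = None
        u_drop = u
    z = u_drop @ state.Wd.T + state.bd
    h = softmax(z)
    if cache is not None:
        cache.update(Xc=Xc, Z1=Z1, pc1=pc1, P1=P1, Z2=Z2, pc2=pc2,
                     P2=P2, u=u, mask=mask, u_drop=u_drop, h=h)
    if single:
        return u[0], h[0]
    return u, h


def _branch_backward(dh_pre: np.ndarray, state: BranchState,
                     config: ModelConfig, cache: dict) -> dict[str, np.ndarray]:
    """Backward pass given dL/dh already mapped through softmax to dL/dz."""
    dz = dh_pre
    dWd = dz.T @ cache["u_drop"]
    dbd = dz.sum(axis=0)
    du = dz @ state.Wd
    if cache["mask"] is not None:
        du = du * cache["mask"]
    dP2 = du.reshape(cache["P2"].shape)
    dS2 = _pool_backward(dP2, cache["pc2"])
    dP1, dW2, db2 = _conv_backward(dS2, cache["Z2"], cache["P1"], state.W2)
    dS1 = _pool_backward(dP1, cache["pc1"])
    _, dW1, db1 = _conv_backward(dS1, cache["Z1"], cache["Xc"], state.W1)
    return {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2,
            "Wd": dWd, "bd": dbd}


def _softmax_vjp(h: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Map dL/dh to dL/dz through the softmax Jacobian (batched)."""
    return h * (g - np.sum(g * h, axis=-1, keepdims=True))


def finite_difference_check(config: ModelConfig, width: int = 16,
                            seed: int = 0, n_per_param: int = 4,
                            eps: float = 1e-6) -> tuple[float, int, int]:
    """Compare analytic gradients of the training loss with central
    finite differences on sampled weights of one branch.

    The loss is piecewise smooth: at a ReLU kink or a pooling-argmax tie
    the finite-difference quotient averages two linear regimes and is
    not a derivative estimate, so sampled points whose activation
    pattern differs between the +eps and -eps evaluations are skipped.
    (Such points are common at zero bias, where windows covering only
    zero padding sit exactly on the kink.)

    Returns (max relative error over checked points, n checked,
    n skipped as non-differentiable).
    """
    cfg = ModelConfig(**{**config.__dict__, "dropout_rate": 0.0})
    rng = np.random.default_rng(seed)
    state = init_branch(cfg, width, rng)
    # nudge biases off the exactly-zero kink set
    state.b1[:] = rng.uniform(-0.05, 0.05, state.b1.shape)
    state.b2[:] = rng.uniform(-0.05, 0.05, state.b2.shape)
    X = rng.random((4, 5, width))
    y = np.zeros((4, 2))
    y[np.arange(4), rng.integers(0, 2, 4)] = 1.0
    weight = 0.5

    def evaluate() -> tuple[float, tuple, dict]:
        cache: dict = {}
        branch_forward(X, state, cfg, cache=cache)
        loss = weight * float(np.sum((cache["h"] - y) ** 2))
        pattern = (cache["Z1"] > 0, cache["Z2"] > 0,
                   cache["pc1"][0].copy(), cache["pc2"][0].copy())
        return loss, pattern, cache

    _, _, cache = evaluate()
    dz = _softmax_vjp(cache["h"], weight * 2.0 * (cache["h"] - y))
    grads = _branch_backward(dz, state, cfg, cache)

    worst, checked, skipped = 0.0, 0, 0
    for name, arr in state.params().items():
        flat = arr.ravel()
        for idx in rng.choice(flat.size, size=min(n_per_param, flat.size),
                              replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            lp, pat_p, _ = evaluate()
            flat[idx] = orig - eps
            lm, pat_m, _ = evaluate()
            flat[idx] = orig
            if not all(np.array_equal(a, b)
                       for a, b in zip(pat_p, pat_m)):
                skipped += 1
                continue
            numeric = (lp - lm) / (2 * eps)
            analytic = float(grads[name].ravel()[idx])
            denom = max(abs(numeric), abs(analytic), 1e-8)
            worst = max(worst, abs(numeric - analytic) / denom)
            checked += 1
    return worst, checked, skipped


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float) -> None:
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mh = self.m[k] / (1 - b1 ** self.t)
            vh = self.v[k] / (1 - b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


@dataclass
class TrainingSet:
    """Labelled pairs plus the embedding builder they are drawn from."""

    context: EmbeddingContext
    drugs: np.ndarray
    diseases: np.ndarray
    labels: np.ndarray  # {0, 1}, 1 = associated

    def __post_init__(self) -> None:
        self.drugs = np.asarray(self.drugs, dtype=int)
        self.diseases = np.asarray(self.diseases, dtype=int)
        self.labels = np.asarray(self.labels, dtype=int)
        if len({self.drugs.size, self.diseases.size, self.labels.size}) != 1:
            raise ValueError("drugs, diseases and labels must be equal length")


class HeteroDualNet:
    """The trained (or trainable) dual-branch model."""

    def __init__(self, config: ModelConfig, width: int) -> None:
        self.config = config
        self.width = width
        self.left: BranchState | None = None
        self.right: BranchState | None = None
        self.loss_history: list[float] = []

    # -- lifecycle ---------------------------------------------------------

    def initialize(self, rng: np.random.Generator) -> None:
        self.left = init_branch(self.config, self.width, rng)
        self.right = init_branch(self.config, self.width, rng)

    @property
    def is_trained(self) -> bool:
        return self.left is not None

    def _require_trained(self) -> None:
        if not self.is_trained:
            raise RuntimeError("model has not been initialized/trained")

    # -- training ----------------------------------------------------------

    def _batch_step(self, XL: np.ndarray, XN: np.ndarray, y: np.ndarray,
                    rng: np.random.Generator, optimizers) -> float:
        cfg = self.config
        caches = ({}, {})
        _, hL = branch_forward(XL, self.left, cfg, training=True, rng=rng,
                               cache=caches[0])
        _, hR = branch_forward(XN, self.right, cfg, training=True, rng=rng,
                               cache=caches[1])
        B = y.shape[0]
        loss = (cfg.alpha * np.sum((hL - y) ** 2)
                + (1 - cfg.alpha) * np.sum((hR - y) ** 2)) / B
        for h, state, cache, weight, opt in (
                (hL, self.left, caches[0], cfg.alpha, optimizers[0]),
                (hR, self.right, caches[1], 1 - cfg.alpha, optimizers[1])):
            if weight == 0.0:
                continue
            g = weight * 2.0 * (h - y) / B
            dz = _softmax_vjp(h, g)
            grads = _branch_backward(dz, state, cfg, cache)
            opt.step(state.params(), grads)
        return float(loss)

    def fit(self, data: TrainingSet) -> "HeteroDualNet":
        cfg = self.config
        labels = data.labels
        if labels.min() == labels.max():
            raise ValueError("training set must contain both associated and "
                             "unassociated pairs")
        rng = np.random.default_rng(cfg.seed)
        if not self.is_trained:
            self.initialize(rng)
        opts = (_Adam(self.left.params(), cfg.learning_rate),
                _Adam(self.right.params(), cfg.learning_rate))
        n = labels.size
        y = np.zeros((n, 2))
        y[np.arange(n), 1 - labels] = 1.0  # column 0 = associated
        ctx = data.context
        self.loss_history = []
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                XL = ctx.build_batch(data.drugs[idx], data.diseases[idx],
                                     "original")
                XN = ctx.build_batch(data.drugs[idx], data.diseases[idx],
                                     "neighbor")
                epoch_loss += self._batch_step(XL, XN, y[idx], rng,
                                               opts) * idx.size
            self.loss_history.append(epoch_loss / n)
            if self._plateaued():
                break
        return self

    def _plateaued(self) -> bool:
        p = self.config.plateau_patience
        hist = self.loss_history
        if len(hist) <= p:
            return False
        return hist[-p - 1] - min(hist[-p:]) < self.config.plateau_tol

    # -- inference ---------------------------------------------------------

    def score_batch(self, ctx: EmbeddingContext, drugs: np.ndarray,
                    diseases: np.ndarray, chunk: int = 256) -> np.ndarray:
        """Fused association probabilities for index arrays."""
        self._require_trained()
        drugs = np.asarray(drugs, dtype=int)
        diseases = np.asarray(diseases, dtype=int)
        out = np.empty(drugs.size)
        for s in range(0, drugs.size, chunk):
            dl = slice(s, s + chunk)
            XL = ctx.build_batch(drugs[dl], diseases[dl], "original")
            XN = ctx.build_batch(drugs[dl], diseases[dl], "neighbor")
            _, hL = branch_forward(XL, self.left, self.config)
            _, hR = branch_forward(XN, self.right, self.config)
            out[dl] = fuse_scores(hL, hR, self.config.alpha)[:, 0]
        return out

    def predict(self, ctx: EmbeddingContext, drug_index: int,
                disease_index: int) -> float:
        """Fused probability that the drug treats the disease."""
        return float(self.score_batch(ctx, np.array([drug_index]),
                                      np.array([disease_index]))[0])

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        self._require_trained()
        arrays = {}
        for side, st in (("L", self.left), ("R", self.right)):
            for k, v in st.params().items():
                arrays[f"{side}_{k}"] = v
        cfg = asdict(self.config)
        np.savez(path, __config__=json.dumps({"config": cfg,
                                              "width": self.width}),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path, expected_width: int | None = None
             ) -> "HeteroDualNet":
        with np.load(path, allow_pickle=False) as zf:
            meta = json.loads(str(zf["__config__"]))
            cfg = ModelConfig(**meta["config"])
            model = cls(cfg, meta["width"])
            model.left = BranchState(*(zf[f"L_{k}"] for k in
                                       ("W1", "b1", "W2", "b2", "Wd", "bd")))
            model.right = BranchState(*(zf[f"R_{k}"] for k in
                                        ("W1", "b1", "W2", "b2", "Wd", "bd")))
        if expected_width is not None and model.width != expected_width:
            raise ConfigurationError(
                f"checkpoint built for embedding width {model.width}, "
                f"dataset has width {expected_width}")
        if model.left.Wd.shape[1] != flat_features(cfg, model.width):
            raise ConfigurationError("checkpoint parameter shapes disagree "
                                     "with its own configuration")
        return model


def train(data: TrainingSet, config: ModelConfig) -> HeteroDualNet:
    """Train a fresh model on the labelled pair set."""
    model = HeteroDualNet(config, data.context.width)
    return model.fit(data)
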