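"""Bipartite graph-convolutional encoder trained by adjacency reconstruction.

Two node sets (microbes, diseases) carry fused similarity matrices as
initial features.  A linear projection maps both to a common width h1; each
graph-convolution layer then combines a neighbourhood-aggregation term

    NM = P_tilde @ H_D @ W1,        ND = P_tilde.T @ H_M @ W1,

with a local-structure term

    GM = ((P_tilde @ H_D) * H_M) @ W2 + b1,
    GD = ((P_tilde.T @ H_M) * H_D) @ W2 + b1,

followed by ReLU, where P_tilde = D1^{-1/2} Y D2^{-1/2} is the
degree-normalised bipartite adjacency (degrees + 1, so normalisation never
divides by zero).  Two layers are used by default (h1=256 then h2=128) to
avoid over-smoothing.  The encoder is trained by reconstructing Y through
logistic(LM @ LD.T) with a balanced binary cross-entropy: all positive pairs
plus an equally sized negative set resampled uniformly each epoch.

The network is small enough that full-batch training with explicit NumPy
forward/backward passes and an Adam update is both fast and exactly
reproducible; embeddings returned after training are computed without
dropout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .core_data import AssociationNetwork

__all__ = [
    "GCNConfig",
    "GCNParameters",
    "GCNEmbeddings",
    "normalized_adjacency",
    "init_parameters",
    "gcn_forward",
    "reconstruct",
    "train_gcn",
]

_EPS = 1e-7


@dataclass(frozen=True)
class GCNConfig:
    """Widths, depth and optimisation settings of the encoder.

    h1/h2 default to 256/128 (hidden and output widths); two layers;
    dropout 0.5 between layers during training; 1000 Adam epochs at
    learning rate 0.001.  ``loss`` selects the reconstruction objective:
    "bce" (default) or "literal" for the non-likelihood variant
    sum(1 - log yhat) over negatives.  ``resample_negatives=False`` fixes
    the epoch-0 negative set for the whole run.
    """

    h1: int = 256
    h2: int = 128
    layers: int = 2
    dropout: float = 0.5
    epochs: int = 1000
    learning_rate: float = 0.001
    seed: int = 0
    loss: str = "bce"
    resample_negatives: bool = True

    def __post_init__(self) -> None:
        if self.layers < 1 or self.h1 < 1 or self.h2 < 1:
            raise ValueError("layers, h1, h2 must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.loss not in ("bce", "literal"):
            raise ValueError("loss must be 'bce' or 'literal'")


@dataclass
class GCNParameters:
    """Learnable arrays: input projections plus per-layer (W1, W2, b1)."""

    W0_M: np.ndarray
    W0_D: np.ndarray
    b_M: np.ndarray
    b_D: np.ndarray
    W1: list[np.ndarray]
    W2: list[np.ndarray]
    b1: list[np.ndarray]

    def flat(self) -> list[np.ndarray]:
        return [self.W0_M, self.W0_D, self.b_M, self.b_D, *self.W1, *self.W2, *self.b1]


@dataclass(frozen=True)
class GCNEmbeddings:
    """Low-rank node features: LM (microbes x h2), LD (diseases x h2)."""

    LM: np.ndarray
    LD: np.ndarray


def normalized_adjacency(Y: np.ndarray) -> np.ndarray:
    """Degree-normalised bipartite adjacency D1^{-1/2} Y D2^{-1/2}.

    D1 = diag(row sums + 1), D2 = diag(column sums + 1); the +1 keeps both
    invertible for isolated nodes, and every entry lies in [0, 1).
    """
    Y = np.asarray(Y, dtype=float)
    d1 = Y.sum(axis=1) + 1.0
    d2 = Y.sum(axis=0) + 1.0
    return Y / np.sqrt(np.outer(d1, d2))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _layer_widths(cfg: GCNConfig) -> list[tuple[int, int]]:
    """(in, out) width of each graph-conv layer: h1 -> ... -> h1 -> h2."""
    widths = [cfg.h1] * cfg.layers + [cfg.h2]
    return [(widths[t], widths[t + 1]) for t in range(cfg.layers)]


def init_parameters(n_m: int, n_d: int, cfg: GCNConfig) -> GCNParameters:
    """Seeded Glorot-uniform weights, zero biases."""
    rng = np.random.default_rng(cfg.seed)
    W1, W2, b1 = [], [], []
    for w_in, w_out in _layer_widths(cfg):
        W1.append(_glorot(rng, w_in, w_out))
        W2.append(_glorot(rng, w_in, w_out))
        b1.append(np.zeros(w_out))
    return GCNParameters(
        W0_M=_glorot(rng, n_m, cfg.h1),
        W0_D=_glorot(rng, n_d, cfg.h1),
        b_M=np.zeros(cfg.h1),
        b_D=np.zeros(cfg.h1),
        W1=W1,
        W2=W2,
        b1=b1,
    )


def gcn_forward(
    params: GCNParameters,
    cfg: GCNConfig,
    FuM: np.ndarray,
    FuD: np.ndarray,
    P: np.ndarray,
    *,
    training: bool = False,
    rng: np.random.Generator | None = None,
    cache: dict | None = None,
) -> GCNEmbeddings:
    """Forward pass; set ``training=True`` to apply inverted dropout to the
    inter-layer activations (requires ``rng``).  ``cache`` (if supplied)
    collects intermediates for the backward pass.
    """
    FuM = np.asarray(FuM, dtype=float)
    FuD = np.asarray(FuD, dtype=float)
    if FuM.shape[1] != params.W0_M.shape[0] or FuD.shape[1] != params.W0_D.shape[0]:
        raise ValueError("feature width does not match projection weights")
    H_M = FuM @ params.W0_M + params.b_M
    H_D = FuD @ params.W0_D + params.b_D

    c = cache if cache is not None else {}
    c["FuM"], c["FuD"], c["P"] = FuM, FuD, P
    c["layers"] = []
    keep = 1.0 - cfg.dropout
    for t in range(cfg.layers):
        lc: dict = {}
        # dropout sits between graph-conv layers, not on the projection
        if training and cfg.dropout > 0 and t > 0:
            if rng is None:
                raise ValueError("training-mode forward pass needs an rng for dropout")
            lc["mask_M"] = (rng.random(H_M.shape) < keep) / keep
            lc["mask_D"] = (rng.random(H_D.shape) < keep) / keep
            H_M = H_M * lc["mask_M"]
            H_D = H_D * lc["mask_D"]
        lc["H_M"], lc["H_D"] = H_M, H_D
        A_M = P @ H_D          # aggregated disease features per microbe
        A_D = P.T @ H_M
        U_M = A_M * H_M        # local-structure gating
        U_D = A_D * H_D
        Z_M = A_M @ params.W1[t] + U_M @ params.W2[t] + params.b1[t]
        Z_D = A_D @ params.W1[t] + U_D @ params.W2[t] + params.b1[t]
        lc.update(A_M=A_M, A_D=A_D, U_M=U_M, U_D=U_D, Z_M=Z_M, Z_D=Z_D)
        H_M = np.maximum(Z_M, 0.0)
        H_D = np.maximum(Z_D, 0.0)
        c["layers"].append(lc)
    return GCNEmbeddings(LM=H_M, LD=H_D)


def reconstruct(emb: GCNEmbeddings) -> np.ndarray:
    """Reconstructed association probabilities logistic(LM @ LD.T)."""
    if emb.LM.shape[1] != emb.LD.shape[1]:
        raise ValueError("embedding widths differ")
    return expit(emb.LM @ emb.LD.T)


def _backward(
    params: GCNParameters,
    cfg: GCNConfig,
    cache: dict,
    dH_M: np.ndarray,
    dH_D: np.ndarray,
) -> GCNParameters:
    """Gradients of the loss w.r.t. all parameters, given gradients at the
    final activations.  Mirrors ``gcn_forward`` exactly."""
    P = cache["P"]
    gW1 = [np.zeros_like(w) for w in params.W1]
    gW2 = [np.zeros_like(w) for w in params.W2]
    gb1 = [np.zeros_like(b) for b in params.b1]
    for t in reversed(range(cfg.layers)):
        lc = cache["layers"][t]
        dZ_M = dH_M * (lc["Z_M"] > 0)
        dZ_D = dH_D * (lc["Z_D"] > 0)
        gW1[t] = lc["A_M"].T @ dZ_M + lc["A_D"].T @ dZ_D
        gW2[t] = lc["U_M"].T @ dZ_M + lc["U_D"].T @ dZ_D
        gb1[t] = dZ_M.sum(axis=0) + dZ_D.sum(axis=0)
        dA_M = dZ_M @ params.W1[t].T
        dA_D = dZ_D @ params.W1[t].T
        dU_M = dZ_M @ params.W2[t].T
        dU_D = dZ_D @ params.W2[t].T
        dA_M += dU_M * lc["H_M"]
        dA_D += dU_D * lc["H_D"]
        dH_M = dU_M * lc["A_M"]
        dH_D = dU_D * lc["A_D"]
        dH_D += P.T @ dA_M
        dH_M += P @ dA_D
        if "mask_M" in lc:
            dH_M = dH_M * lc["mask_M"]
            dH_D = dH_D * lc["mask_D"]
    return GCNParameters(
        W0_M=cache["FuM"].T @ dH_M,
        W0_D=cache["FuD"].T @ dH_D,
        b_M=dH_M.sum(axis=0),
        b_D=dH_D.sum(axis=0),
        W1=gW1,
        W2=gW2,
        b1=gb1,
    )


def _reconstruction_loss_and_grad(
    emb: GCNEmbeddings,
    pos: np.ndarray,
    neg: np.ndarray,
    loss_kind: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss over E u Neg and gradients w.r.t. LM, LD.

    The default "bce" objective is
    -(1/n)(sum_E log yhat + sum_Neg log(1 - yhat)); "literal" replaces the
    negative term with (1 - log yhat).
    """
    n = len(pos)
    S_pos = np.einsum("ij,ij->i", emb.LM[pos[:, 0]], emb.LD[pos[:, 1]])
    S_neg = np.einsum("ij,ij->i", emb.LM[neg[:, 0]], emb.LD[neg[:, 1]])
    y_pos = np.clip(expit(S_pos), _EPS, 1 - _EPS)
    y_neg = np.clip(expit(S_neg), _EPS, 1 - _EPS)
    if loss_kind == "bce":
        loss = -(np.log(y_pos).sum() + np.log1p(-y_neg).sum()) / n
        g_neg = y_neg / n           # d/dS of -(1/n) log(1-sigmoid(S))
    else:  # literal: -(1/n) sum (1 - log yhat) over negatives
        loss = -(np.log(y_pos).sum() + (1.0 - np.log(y_neg)).sum()) / n
        g_neg = (1.0 - y_neg) / n   # d/dS of (1/n) log sigmoid(S)
    g_pos = -(1.0 - y_pos) / n      # d/dS of -(1/n) log sigmoid(S)

    dLM = np.zeros_like(emb.LM)
    dLD = np.zeros_like(emb.LD)
    np.add.at(dLM, pos[:, 0], g_pos[:, None] * emb.LD[pos[:, 1]])
    np.add.at(dLD, pos[:, 1], g_pos[:, None] * emb.LM[pos[:, 0]])
    np.add.at(dLM, neg[:, 0], g_neg[:, None] * emb.LD[neg[:, 1]])
    np.add.at(dLD, neg[:, 1], g_neg[:, None] * emb.LM[neg[:, 0]])
    return float(loss), dLM, dLD


class _Adam:
    """Standard Adam on a list of parameter arrays, updated in place."""

    def __init__(self, arrays: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.arrays = arrays
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for a, g, m, v in zip(self.arrays, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            a -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)

    def set_lr(self, lr: float) -> None:
        self.lr = lr


def train_gcn(
    net: AssociationNetwork,
    FuM: np.ndarray,
    FuD: np.ndarray,
    cfg: GCNConfig | None = None,
    *,
    return_history: bool = False,
) -> GCNEmbeddings | tuple[GCNEmbeddings, list[float]]:
    """Train the encoder by balanced reconstruction of Y; returns final
    embeddings computed without dropout (optionally with the per-epoch loss
    history).  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or GCNConfig()
    pos = np.argwhere(net.Y == 1)
    if len(pos) == 0:
        raise ValueError("network has no edges; nothing to reconstruct")
    zeros = np.argwhere(net.Y == 0)
    if len(zeros) == 0:
        raise ValueError("network has no non-edges; cannot sample negatives")
    rng = np.random.default_rng(cfg.seed)
    params = init_parameters(net.n_microbes, net.n_diseases, cfg)
    P = normalized_adjacency(net.Y)
    opt = _Adam(params.flat(), cfg.learning_rate)

    n = len(pos)
    neg = zeros[rng.choice(len(zeros), size=min(n, len(zeros)), replace=False)]
    history: list[float] = []
    for _ in range(cfg.epochs):
        if cfg.resample_negatives:
            neg = zeros[rng.choice(len(zeros), size=min(n, len(zeros)), replace=False)]
        cache: dict = {}
        emb = gcn_forward(params, cfg, FuM, FuD, P, training=True, rng=rng, cache=cache)
        loss, dLM, dLD = _reconstruction_loss_and_grad(emb, pos, neg, cfg.loss)
        grads = _backward(params, cfg, cache, dLM, dLD)
        opt.step(grads.flat())
        history.append(loss)

    emb = gcn_forward(params, cfg, FuM, FuD, P, training=False)
    if return_history:
        return emb, history
    return emb
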