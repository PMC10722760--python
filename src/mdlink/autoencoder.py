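"""Deep sparse auto-encoder extracting high-rank pair features.

Each microbe-disease pair is initially represented by the concatenation of
one fused disease-similarity row and one fused microbe-similarity row (all
entries in [0, 1]).  A 4-layer sigmoid encoder compresses this vector to a
144-d code and a mirrored 4-layer sigmoid decoder reconstructs the input;
the 144-d bottleneck code is the pair's high-rank feature vector.

The training objective couples the mean squared reconstruction error with a
KL-divergence term between the (epsilon-smoothed, sum-normalised) input and
reconstruction, weighted by ``kl_weight``; the KL term pushes the
reconstruction to match the input's distribution of mass across features,
not only its pointwise values.  Optimisation is full-batch Adam with a
reduce-on-plateau learning-rate schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "DAEConfig",
    "DAEParameters",
    "default_encoder_dims",
    "init_dae",
    "dae_forward",
    "dae_loss",
    "dae_loss_grad",
    "train_dae",
    "encode",
]

#: Layer widths used for the reference 1311-d input (134 + 1177).
REFERENCE_ENCODER_DIMS = (1311, 1152, 576, 288, 144)


def default_encoder_dims(input_width: int, code_width: int = 144, n_layers: int = 4) -> tuple[int, ...]:
    """Encoder layer widths for an arbitrary input width.

    The 1311-wide reference input uses the fixed ladder
    1311 -> 1152 -> 576 -> 288 -> 144; any other width interpolates
    geometrically from the input down to the code over ``n_layers`` steps.
    """
    if input_width == REFERENCE_ENCODER_DIMS[0] and code_width == 144 and n_layers == 4:
        return REFERENCE_ENCODER_DIMS
    if input_width < 1 or code_width < 1:
        raise ValueError("widths must be positive")
    ratios = np.linspace(0, 1, n_layers + 1)
    dims = np.rint(
        np.exp(np.log(input_width) * (1 - ratios) + np.log(code_width) * ratios)
    ).astype(int)
    dims[0], dims[-1] = input_width, code_width
    return tuple(int(d) for d in dims)


@dataclass(frozen=True)
class DAEConfig:
    """Auto-encoder architecture and optimisation settings.

    ``encoder_dims`` lists widths input..code (4 transitions); the decoder
    mirrors it.  Defaults: 150 epochs, initial learning rate 0.01, plateau
    reduction (factor 0.5, patience 10), KL weight 1.0 with epsilon 1e-7.
    """

    encoder_dims: tuple[int, ...] = REFERENCE_ENCODER_DIMS
    epochs: int = 150
    initial_learning_rate: float = 0.01
    kl_weight: float = 1.0
    kl_epsilon: float = 1e-7
    lr_factor: float = 0.5
    lr_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.encoder_dims) < 2 or any(d < 1 for d in self.encoder_dims):
            raise ValueError("encoder_dims must list >= 2 positive widths")
        if self.kl_weight < 0 or self.kl_epsilon <= 0:
            raise ValueError("kl_weight must be >= 0 and kl_epsilon > 0")

    @property
    def decoder_dims(self) -> tuple[int, ...]:
        return tuple(reversed(self.encoder_dims))

    @classmethod
    def for_input_width(cls, width: int, **kwargs) -> "DAEConfig":
        return cls(encoder_dims=default_encoder_dims(width), **kwargs)


@dataclass
class DAEParameters:
    """Weights/biases of encoder and decoder (lists of (W, b) per layer)."""

    enc_W: list[np.ndarray]
    enc_b: list[np.ndarray]
    dec_W: list[np.ndarray]
    dec_b: list[np.ndarray]

    def flat(self) -> list[np.ndarray]:
        return [*self.enc_W, *self.enc_b, *self.dec_W, *self.dec_b]

    @property
    def input_width(self) -> int:
        return self.enc_W[0].shape[0]

    @property
    def code_width(self) -> int:
        return self.enc_W[-1].shape[1]


def init_dae(cfg: DAEConfig) -> DAEParameters:
    """Seeded Glorot-uniform weights, zero biases, mirrored decoder."""
    rng = np.random.default_rng(cfg.seed)

    def glorot(fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    enc = cfg.encoder_dims
    dec = cfg.decoder_dims
    return DAEParameters(
        enc_W=[glorot(enc[i], enc[i + 1]) for i in range(len(enc) - 1)],
        enc_b=[np.zeros(enc[i + 1]) for i in range(len(enc) - 1)],
        dec_W=[glorot(dec[i], dec[i + 1]) for i in range(len(dec) - 1)],
        dec_b=[np.zeros(dec[i + 1]) for i in range(len(dec) - 1)],
    )


def dae_forward(
    params: DAEParameters, x: np.ndarray, cache: dict | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Encode then decode; returns (code, reconstruction).

    All layers are sigmoid; accepts a single row or a batch.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != params.input_width:
        raise ValueError(
            f"input width {x.shape[1]} != expected {params.input_width}"
        )
    c = cache if cache is not None else {}
    c["acts"] = [x]
    h = x
    for W, b in zip(params.enc_W, params.enc_b):
        h = expit(h @ W + b)
        c["acts"].append(h)
    code = h
    for W, b in zip(params.dec_W, params.dec_b):
        h = expit(h @ W + b)
        c["acts"].append(h)
    return code, h


def _normalize(v: np.ndarray, eps: float) -> np.ndarray:
    v = v + eps
    return v / v.sum(axis=-1, keepdims=True)


def dae_loss(
    x: np.ndarray, x_rec: np.ndarray, kl_weight: float = 1.0, kl_epsilon: float = 1e-7
) -> float:
    """MSE(x, x_rec) + kl_weight * KL(norm(x) || norm(x_rec)).

    Both vectors are epsilon-smoothed and normalised to sum 1 before the KL
    term (row-wise for batches, then averaged).  Non-negative; zero exactly
    at perfect reconstruction.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x_rec = np.atleast_2d(np.asarray(x_rec, dtype=float))
    if x.shape != x_rec.shape:
        raise ValueError("shape mismatch between input and reconstruction")
    mse = float(np.mean((x - x_rec) ** 2))
    p = _normalize(x, kl_epsilon)
    q = _normalize(x_rec, kl_epsilon)
    kl = float(np.mean(np.sum(p * np.log(p / q), axis=-1)))
    return mse + kl_weight * kl


def dae_loss_grad(
    x: np.ndarray, x_rec: np.ndarray, kl_weight: float, kl_epsilon: float
) -> np.ndarray:
    """Analytic gradient of ``dae_loss`` w.r.t. the reconstruction."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x_rec = np.atleast_2d(np.asarray(x_rec, dtype=float))
    n_rows, width = x.shape
    g = 2.0 * (x_rec - x) / (n_rows * width)  # MSE part
    if kl_weight > 0:
        p = _normalize(x, kl_epsilon)
        q_raw = x_rec + kl_epsilon
        s = q_raw.sum(axis=-1, keepdims=True)
        q = q_raw / s
        # dKL/dx_rec_j = (1 - p_j / q_j) / s   (row-wise), averaged over rows
        g = g + kl_weight * (1.0 - p / q) / s / n_rows
    return g


def _backward(params: DAEParameters, cache: dict, g_out: np.ndarray) -> DAEParameters:
    """Backprop through the sigmoid chain given dLoss/dReconstruction."""
    acts = cache["acts"]
    n_enc = len(params.enc_W)
    grads_W: list[np.ndarray] = []
    grads_b: list[np.ndarray] = []
    d = g_out
    all_W = params.enc_W + params.dec_W
    for li in reversed(range(len(all_W))):
        out = acts[li + 1]
        delta = d * out * (1.0 - out)  # sigmoid'
        grads_W.append(acts[li].T @ delta)
        grads_b.append(delta.sum(axis=0))
        d = delta @ all_W[li].T
    grads_W.reverse()
    grads_b.reverse()
    return DAEParameters(
        enc_W=grads_W[:n_enc],
        enc_b=grads_b[:n_enc],
        dec_W=grads_W[n_enc:],
        dec_b=grads_b[n_enc:],
    )


def train_dae(
    X: np.ndarray, cfg: DAEConfig | None = None, *, return_history: bool = False
) -> DAEParameters | tuple[DAEParameters, list[float]]:
    """Full-batch Adam training of the auto-encoder on the rows of X.

    The learning rate starts at ``initial_learning_rate`` and is halved when
    the training loss has not improved for ``lr_patience`` epochs.
    Deterministic given ``cfg.seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        raise ValueError("empty training matrix")
    cfg = cfg or DAEConfig.for_input_width(X.shape[1])
    if X.shape[1] != cfg.encoder_dims[0]:
        raise ValueError(
            f"input width {X.shape[1]} != encoder_dims[0] = {cfg.encoder_dims[0]}"
        )
    params = init_dae(cfg)

    from .gcn import _Adam  # shared optimiser

    opt = _Adam(params.flat(), cfg.initial_learning_rate)
    best = np.inf
    stale = 0
    history: list[float] = []
    for _ in range(cfg.epochs):
        cache: dict = {}
        _, x_rec = dae_forward(params, X, cache)
        loss = dae_loss(X, x_rec, cfg.kl_weight, cfg.kl_epsilon)
        g_out = dae_loss_grad(X, x_rec, cfg.kl_weight, cfg.kl_epsilon)
        grads = _backward(params, cache, g_out)
        opt.step(grads.flat())
        history.append(loss)
        if loss < best - 1e-12:
            best = loss
            stale = 0
        else:
            stale += 1
            if stale > cfg.lr_patience:
                opt.set_lr(opt.lr * cfg.lr_factor)
                stale = 0
    if return_history:
        return params, history
    return params


def encode(params: DAEParameters, X: np.ndarray) -> np.ndarray:
    """Row-wise bottleneck codes (high-rank pair features); pure function."""
    code, _ = dae_forward(params, X)
    return code


def save_params(params: DAEParameters, path) -> None:
    """Serialize encoder+decoder parameters to one portable .npz file with a
    JSON header recording the layer dimensions."""
    import json

    header = {
        "encoder_dims": [params.input_width]
        + [W.shape[1] for W in params.enc_W],
        "n_enc": len(params.enc_W),
        "n_dec": len(params.dec_W),
    }
    arrays = {"header": np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)}
    for i, (W, b) in enumerate(zip(params.enc_W, params.enc_b)):
        arrays[f"enc_W{i}"], arrays[f"enc_b{i}"] = W, b
    for i, (W, b) in enumerate(zip(params.dec_W, params.dec_b)):
        arrays[f"dec_W{i}"], arrays[f"dec_b{i}"] = W, b
    np.savez(path, **arrays)


def load_params(path) -> DAEParameters:
    """Inverse of :func:`save_params`."""
    import json

    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        return DAEParameters(
            enc_W=[z[f"enc_W{i}"] for i in range(header["n_enc"])],
            enc_b=[z[f"enc_b{i}"] for i in range(header["n_enc"])],
            dec_W=[z[f"dec_W{i}"] for i in range(header["n_dec"])],
            dec_b=[z[f"dec_b{i}"] for i in range(header["n_dec"])],
        )
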