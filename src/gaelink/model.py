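"""Two collaboratively trained graph autoencoders with an attention score head.

One autoencoder propagates the association matrix over the row-entity
(miRNA) graph, the other propagates its transpose over the column-entity
(disease) graph. The two reconstructions are blended into a score matrix F,
and a rowwise-softmax attention score T couples the two embeddings.
The joint objective is

    1/2 ||Y - T||_F^2  +  beta * (alpha ||Y - Fm||_F^2 + (1-alpha) ||Y - Fd^T||_F^2)
    +  lam * sum ||W||_F^2

optimized by Adam over all eight weight matrices. The network is small
enough that forward and backward passes are hand-written dense NumPy; this
keeps the objective literal and makes the gradients directly checkable by
finite differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError, DataError, DivergenceError
from .graph import NormalizedGraph
from .types import AssociationMatrix

__all__ = [
    "Hyperparams",
    "ModelState",
    "ScoreBundle",
    "encode",
    "decode",
    "combine_scores",
    "attention_score",
    "total_loss",
    "forward",
    "loss_and_grads",
    "train",
    "init_state",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = "gaelink-checkpoint-1"

# consecutive sub-tolerance epochs required before declaring convergence
CONVERGENCE_PATIENCE = 10

WEIGHT_KEYS = ("m_w0", "m_w1", "m_w2", "m_w3", "d_w0", "d_w1", "d_w2", "d_w3")


@dataclass(frozen=True)
class Hyperparams:
    """All knobs of the model and its training loop."""

    alpha: float = 0.5
    beta: float = 1.0
    lam: float = 1e-7
    hidden_dim: int = 64
    inter_dim: int = 256
    dropout: float = 0.5
    learning_rate: float = 0.01
    max_epochs: int = 200
    tol: float = 1e-4
    seed: int = 0
    attention_scale: str = "dim"
    loss_mode: str = "full"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.beta < 0 or self.lam < 0:
            raise ConfigError("beta and lam must be nonnegative")
        if self.hidden_dim < 1 or self.inter_dim < 1:
            raise ConfigError("hidden_dim and inter_dim must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError(f"dropout must lie in [0, 1), got {self.dropout}")
        if not (self.learning_rate > 0 and np.isfinite(self.learning_rate)):
            raise ConfigError("learning_rate must be positive and finite")
        if self.max_epochs < 1:
            raise ConfigError("max_epochs must be positive")
        if self.attention_scale not in ("dim", "sqrt_dim"):
            raise ConfigError(
                f"attention_scale must be 'dim' or 'sqrt_dim', got {self.attention_scale!r}"
            )
        if self.loss_mode not in ("full", "attention_only", "reconstruction_only"):
            raise ConfigError(f"unknown loss_mode {self.loss_mode!r}")

    def replace(self, **kwargs) -> "Hyperparams":
        return replace(self, **kwargs)


@dataclass
class ModelState:
    """The eight weight matrices of the two autoencoders.

    Row-side encoder/decoder: w0 (n x inter), w1 (inter x d), w2 (d x inter),
    w3 (inter x n); column-side analogous with m in place of n.
    """

    weights: dict[str, np.ndarray]
    hyperparams: Hyperparams

    def __post_init__(self) -> None:
        missing = set(WEIGHT_KEYS) - set(self.weights)
        if missing:
            raise DataError(f"missing weight blocks: {sorted(missing)}")
        for key in WEIGHT_KEYS:
            w = np.asarray(self.weights[key], dtype=float)
            if not np.isfinite(w).all():
                raise DataError(f"non-finite entries in weight block {key}")
            self.weights[key] = w

    def copy(self) -> "ModelState":
        return ModelState(
            {k: v.copy() for k, v in self.weights.items()}, self.hyperparams
        )


@dataclass
class ScoreBundle:
    """One dropout-free forward pass: embeddings, reconstructions, scores."""

    Zm: np.ndarray
    Zd: np.ndarray
    Fm: np.ndarray
    Fd: np.ndarray
    F: np.ndarray
    T: np.ndarray
    attention_weights: np.ndarray = field(repr=False, default=None)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_state(m: int, n: int, hp: Hyperparams) -> ModelState:
    """Glorot-uniform initialization of all eight blocks, seeded by hp.seed."""
    rng = np.random.default_rng(hp.seed)
    inter, d = hp.inter_dim, hp.hidden_dim
    weights = {
        "m_w0": _glorot(rng, n, inter),
        "m_w1": _glorot(rng, inter, d),
        "m_w2": _glorot(rng, d, inter),
        "m_w3": _glorot(rng, inter, n),
        "d_w0": _glorot(rng, m, inter),
        "d_w1": _glorot(rng, inter, d),
        "d_w2": _glorot(rng, d, inter),
        "d_w3": _glorot(rng, inter, m),
    }
    return ModelState(weights, hp)


def _check_matmul(a: np.ndarray, b: np.ndarray, what: str) -> None:
    if a.shape[-1] != b.shape[0]:
        raise DataError(f"shape mismatch in {what}: {a.shape} @ {b.shape}")


def encode(
    A: NormalizedGraph | np.ndarray,
    X: np.ndarray,
    W0: np.ndarray,
    W1: np.ndarray,
) -> np.ndarray:
    """tanh(A . ReLU(A X W0) W1): two rounds of propagation over the graph."""
    adj = A.adjacency if isinstance(A, NormalizedGraph) else np.asarray(A)
    if adj.shape[0] != X.shape[0]:
        raise DataError(f"graph size {adj.shape} does not match inputs {X.shape}")
    _check_matmul(X, W0, "encoder layer 0")
    _check_matmul(np.empty((1, W0.shape[1])), W1, "encoder layer 1")
    hidden = np.maximum(adj @ X @ W0, 0.0)
    return np.tanh(adj @ hidden @ W1)


def decode(
    A: NormalizedGraph | np.ndarray,
    Z: np.ndarray,
    W2: np.ndarray,
    W3: np.ndarray,
) -> np.ndarray:
    """sigmoid(A . ReLU(A Z W2) W3): reconstruction from embeddings."""
    adj = A.adjacency if isinstance(A, NormalizedGraph) else np.asarray(A)
    if adj.shape[0] != Z.shape[0]:
        raise DataError(f"graph size {adj.shape} does not match embeddings {Z.shape}")
    _check_matmul(Z, W2, "decoder layer 0")
    _check_matmul(np.empty((1, W2.shape[1])), W3, "decoder layer 1")
    hidden = np.maximum(adj @ Z @ W2, 0.0)
    return _sigmoid(adj @ hidden @ W3)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def combine_scores(Fm: np.ndarray, Fd: np.ndarray, alpha: float) -> np.ndarray:
    """Convex blend alpha * Fm + (1 - alpha) * Fd^T of the two reconstructions."""
    if Fd.T.shape != Fm.shape:
        raise DataError(f"incompatible score shapes {Fm.shape} vs {Fd.shape}")
    if not (0.0 < alpha < 1.0):
        raise ConfigError(f"alpha must lie in (0, 1), got {alpha}")
    return alpha * Fm + (1.0 - alpha) * Fd.T


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    ex = np.exp(shifted)
    return ex / ex.sum(axis=1, keepdims=True)


def _attention_divisor(d: int, scale: str) -> float:
    if scale == "dim":
        return float(d)
    if scale == "sqrt_dim":
        return float(np.sqrt(d))
    raise ConfigError(f"unknown attention scale {scale!r}")


def attention_score(
    Zm: np.ndarray,
    Zd: np.ndarray,
    F: np.ndarray,
    d: int,
    scale: str = "dim",
) -> np.ndarray:
    """Rowwise softmax of scaled embedding dot products, gating F elementwise."""
    if Zm.shape[1] != Zd.shape[1]:
        raise DataError(f"embedding widths differ: {Zm.shape} vs {Zd.shape}")
    if F.shape != (Zm.shape[0], Zd.shape[0]):
        raise DataError(f"score matrix shape {F.shape} does not match embeddings")
    weights = _softmax_rows(Zm @ Zd.T / _attention_divisor(d, scale))
    return weights * F


def total_loss(
    Y: np.ndarray,
    T: np.ndarray,
    Fm: np.ndarray,
    Fd: np.ndarray,
    hp: Hyperparams,
    weights: dict[str, np.ndarray] | None = None,
) -> float:
    """The composite objective; raw sums of squares, no averaging."""
    Y = np.asarray(Y, dtype=float)
    if T.shape != Y.shape or Fm.shape != Y.shape or Fd.T.shape != Y.shape:
        raise DataError("loss inputs must all match the association shape")
    attention_term = 0.5 * float(((Y - T) ** 2).sum())
    recon = hp.alpha * float(((Y - Fm) ** 2).sum()) + (1.0 - hp.alpha) * float(
        ((Y - Fd.T) ** 2).sum()
    )
    penalty = 0.0
    if weights is not None:
        penalty = hp.lam * sum(float((w**2).sum()) for w in weights.values())
    if hp.loss_mode == "full":
        return attention_term + hp.beta * recon + penalty
    if hp.loss_mode == "attention_only":
        return attention_term + penalty
    return hp.beta * recon + penalty


def _dropout_mask(
    rng: np.random.Generator | None, shape: tuple[int, ...], rate: float
) -> np.ndarray | None:
    """Inverted-dropout keep mask already scaled by 1/(1-rate)."""
    if rng is None or rate <= 0.0:
        return None
    return (rng.random(shape) >= rate) / (1.0 - rate)


def _apply(x: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    return x if mask is None else x * mask


def _forward_side(
    adj: np.ndarray,
    X: np.ndarray,
    w0: np.ndarray,
    w1: np.ndarray,
    w2: np.ndarray,
    w3: np.ndarray,
    rate: float,
    rng: np.random.Generator | None,
) -> dict[str, np.ndarray]:
    """One autoencoder; returns every intermediate needed by the backward pass."""
    cache: dict[str, np.ndarray] = {}
    cache["mask_x"] = _dropout_mask(rng, X.shape, rate)
    Xd = _apply(X, cache["mask_x"])
    cache["AXd"] = adj @ Xd
    P0 = cache["AXd"] @ w0
    H0 = np.maximum(P0, 0.0)
    cache["P0"], cache["H0"] = P0, H0
    cache["mask_h0"] = _dropout_mask(rng, H0.shape, rate)
    H0d = _apply(H0, cache["mask_h0"])
    cache["AH0d"] = adj @ H0d
    Z = np.tanh(cache["AH0d"] @ w1)
    cache["Z"] = Z
    cache["mask_z"] = _dropout_mask(rng, Z.shape, rate)
    Zd = _apply(Z, cache["mask_z"])
    cache["AZd"] = adj @ Zd
    P2 = cache["AZd"] @ w2
    H2 = np.maximum(P2, 0.0)
    cache["P2"], cache["H2"] = P2, H2
    cache["mask_h2"] = _dropout_mask(rng, H2.shape, rate)
    H2d = _apply(H2, cache["mask_h2"])
    cache["AH2d"] = adj @ H2d
    cache["Fout"] = _sigmoid(cache["AH2d"] @ w3)
    return cache


def _backward_side(
    adj: np.ndarray,
    cache: dict[str, np.ndarray],
    w1: np.ndarray,
    w2: np.ndarray,
    w3: np.ndarray,
    dF: np.ndarray,
    dZ_extra: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of one autoencoder given dLoss/dFout and dLoss/dZ.

    The adjacency is symmetric, so A^T collapses to A throughout.
    """
    F = cache["Fout"]
    g3 = dF * F * (1.0 - F)
    d_w3 = cache["AH2d"].T @ g3
    dH2d = adj @ (g3 @ w3.T)
    dH2 = _apply(dH2d, cache["mask_h2"])
    g2 = dH2 * (cache["P2"] > 0)
    d_w2 = cache["AZd"].T @ g2
    dZd = adj @ (g2 @ w2.T)
    dZ = _apply(dZd, cache["mask_z"]) + dZ_extra
    g1 = dZ * (1.0 - cache["Z"] ** 2)
    d_w1 = cache["AH0d"].T @ g1
    dH0d = adj @ (g1 @ w1.T)
    dH0 = _apply(dH0d, cache["mask_h0"])
    g0 = dH0 * (cache["P0"] > 0)
    d_w0 = cache["AXd"].T @ g0
    return {"w0": d_w0, "w1": d_w1, "w2": d_w2, "w3": d_w3}


def forward(
    state: ModelState,
    Y: np.ndarray,
    Am: NormalizedGraph,
    Ad: NormalizedGraph,
    rng: np.random.Generator | None = None,
) -> tuple[ScoreBundle, dict]:
    """Full forward pass. Pass ``rng`` to activate dropout (training mode)."""
    hp = state.hyperparams
    Y = np.asarray(Y, dtype=float)
    m, n = Y.shape
    if Am.adjacency.shape != (m, m) or Ad.adjacency.shape != (n, n):
        raise DataError("graph sizes do not match the association matrix")
    rate = hp.dropout if rng is not None else 0.0
    w = state.weights
    cm = _forward_side(
        Am.adjacency, Y, w["m_w0"], w["m_w1"], w["m_w2"], w["m_w3"], rate, rng
    )
    cd = _forward_side(
        Ad.adjacency, Y.T, w["d_w0"], w["d_w1"], w["d_w2"], w["d_w3"], rate, rng
    )
    Zm, Zd = cm["Z"], cd["Z"]
    Fm, Fd = cm["Fout"], cd["Fout"]
    F = combine_scores(Fm, Fd, hp.alpha)
    divisor = _attention_divisor(hp.hidden_dim, hp.attention_scale)
    P = _softmax_rows(Zm @ Zd.T / divisor)
    T = P * F
    bundle = ScoreBundle(Zm=Zm, Zd=Zd, Fm=Fm, Fd=Fd, F=F, T=T, attention_weights=P)
    return bundle, {"m": cm, "d": cd, "P": P, "divisor": divisor}


def loss_and_grads(
    state: ModelState,
    Y: np.ndarray,
    Am: NormalizedGraph,
    Ad: NormalizedGraph,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Objective value and its gradient with respect to every weight block."""
    hp = state.hyperparams
    Y = np.asarray(Y, dtype=float)
    bundle, cache = forward(state, Y, Am, Ad, rng=rng)
    w = state.weights
    loss = total_loss(Y, bundle.T, bundle.Fm, bundle.Fd, hp, weights=w)

    P, divisor = cache["P"], cache["divisor"]
    alpha, beta = hp.alpha, hp.beta
    attention_on = hp.loss_mode in ("full", "attention_only")
    recon_on = hp.loss_mode in ("full", "reconstruction_only")

    dF = np.zeros_like(bundle.F)
    dZm = np.zeros_like(bundle.Zm)
    dZd = np.zeros_like(bundle.Zd)
    if attention_on:
        dT = bundle.T - Y
        dF += dT * P
        dP = dT * bundle.F
        # rowwise softmax jacobian
        dS = P * (dP - (dP * P).sum(axis=1, keepdims=True))
        dZm += dS @ bundle.Zd / divisor
        dZd += dS.T @ bundle.Zm / divisor
    dFm = alpha * dF
    dFdT = (1.0 - alpha) * dF
    if recon_on:
        dFm = dFm + 2.0 * beta * alpha * (bundle.Fm - Y)
        dFdT = dFdT + 2.0 * beta * (1.0 - alpha) * (bundle.Fd.T - Y)

    gm = _backward_side(
        Am.adjacency, cache["m"], w["m_w1"], w["m_w2"], w["m_w3"], dFm, dZm
    )
    gd = _backward_side(
        Ad.adjacency, cache["d"], w["d_w1"], w["d_w2"], w["d_w3"], dFdT.T, dZd
    )
    grads = {f"m_{k}": v for k, v in gm.items()}
    grads.update({f"d_{k}": v for k, v in gd.items()})
    for key in WEIGHT_KEYS:
        grads[key] = grads[key] + 2.0 * hp.lam * w[key]
    return loss, grads


def train(
    Y: AssociationMatrix | np.ndarray,
    Am: NormalizedGraph,
    Ad: NormalizedGraph,
    hp: Hyperparams,
    init: ModelState | None = None,
) -> tuple[ScoreBundle, list[float], ModelState]:
    """Adam-optimize the joint objective; returns scores, loss trace, state.

    The per-epoch trace records the dropout-free objective after each update;
    training stops at ``max_epochs`` or once the relative change of that
    trace has stayed below ``tol`` for ``CONVERGENCE_PATIENCE`` consecutive
    epochs (dropout makes single-epoch plateaus spurious). A non-finite loss
    aborts with :class:`DivergenceError` carrying the epoch index.
    """
    Yv = Y.values if isinstance(Y, AssociationMatrix) else np.asarray(Y, float)
    m, n = Yv.shape
    state = init.copy() if init is not None else init_state(m, n, hp)
    rng = np.random.default_rng(hp.seed + 1) if hp.dropout > 0 else None

    moments1 = {k: np.zeros_like(v) for k, v in state.weights.items()}
    moments2 = {k: np.zeros_like(v) for k, v in state.weights.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    losses: list[float] = []
    quiet_epochs = 0
    for epoch in range(hp.max_epochs):
        loss, grads = loss_and_grads(state, Yv, Am, Ad, rng=rng)
        if not np.isfinite(loss):
            raise DivergenceError(epoch)
        t = epoch + 1
        for key in WEIGHT_KEYS:
            g = grads[key]
            moments1[key] = b1 * moments1[key] + (1 - b1) * g
            moments2[key] = b2 * moments2[key] + (1 - b2) * g * g
            m_hat = moments1[key] / (1 - b1**t)
            v_hat = moments2[key] / (1 - b2**t)
            state.weights[key] -= hp.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        bundle, _ = forward(state, Yv, Am, Ad, rng=None)
        eval_loss = total_loss(Yv, bundle.T, bundle.Fm, bundle.Fd, hp, state.weights)
        if not np.isfinite(eval_loss):
            raise DivergenceError(epoch)
        losses.append(eval_loss)
        if len(losses) >= 2:
            prev = losses[-2]
            if abs(prev - losses[-1]) <= hp.tol * max(abs(prev), 1e-12):
                quiet_epochs += 1
            else:
                quiet_epochs = 0
            if quiet_epochs >= CONVERGENCE_PATIENCE:
                break
    bundle, _ = forward(state, Yv, Am, Ad, rng=None)
    return bundle, losses, state


def save_checkpoint(path: str | Path, state: ModelState) -> None:
    """Portable JSON checkpoint of weights plus hyperparameters."""
    payload = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "hyperparams": {f.name: getattr(state.hyperparams, f.name) for f in fields(Hyperparams)},
        "weights": {k: v.tolist() for k, v in state.weights.items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> ModelState:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != CHECKPOINT_FORMAT_VERSION:
        raise DataError(
            f"unsupported checkpoint format {payload.get('format_version')!r}"
        )
    hp = Hyperparams(**payload["hyperparams"])
    weights = {k: np.asarray(v, dtype=float) for k, v in payload["weights"].items()}
    return ModelState(weights, hp)
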