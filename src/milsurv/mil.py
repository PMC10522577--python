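"""Attention-based multiple-instance model for tile-feature bags.

A patient's K tile features ``f_1..f_K`` (rows of a K x M matrix) are pooled
into one slide-level feature

    z = sum_k a_k f_k,      a_k = softmax_k( w^T tanh(V f_k^T) )

with trainable ``V`` (L x M) and ``w`` (L).  The slide feature feeds a small
fully connected head (M -> 128 -> 64 -> out) with ReLU activations and
dropout p = 0.5 between layers at train time.  The survival head has 60
outputs passed through softplus (one positive hazard mass per month); the
binary head has a single logistic output (five-year death risk).

The model is small enough that forward and backward passes are written
directly in numpy; gradients are verified against finite differences in the
test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import HORIZON, FeatureBag

__all__ = [
    "AttentionParams",
    "HeadParams",
    "MILParams",
    "SlideFeature",
    "init_params",
    "attend_and_pool",
    "predict_hazards",
    "predict_binary_risk",
    "forward_bag",
    "backward_bag",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class AttentionParams:
    V: np.ndarray  # (L, M)
    w: np.ndarray  # (L,)

    def __post_init__(self) -> None:
        if self.V.ndim != 2 or self.w.ndim != 1 or self.V.shape[0] != self.w.shape[0]:
            raise ValueError("attention shapes inconsistent: V is LxM, w is L")


@dataclass
class HeadParams:
    """Fully connected head; ``weights[i]`` maps layer i input to output."""

    weights: list
    biases: list
    activation: str  # 'softplus' (survival) or 'sigmoid' (binary)
    dropout: float = 0.5

    @property
    def n_out(self) -> int:
        return self.weights[-1].shape[0]


@dataclass
class MILParams:
    attention: AttentionParams
    head: HeadParams

    def arrays(self) -> list:
        """Flat list of trainable arrays (views, not copies)."""
        return [self.attention.V, self.attention.w, *self.head.weights, *self.head.biases]

    def copy(self) -> "MILParams":
        att = AttentionParams(self.attention.V.copy(), self.attention.w.copy())
        head = HeadParams(
            [W.copy() for W in self.head.weights],
            [b.copy() for b in self.head.biases],
            self.head.activation,
            self.head.dropout,
        )
        return MILParams(att, head)


@dataclass
class SlideFeature:
    """Pooled slide-level feature with its attention distribution."""

    z: np.ndarray
    attention: np.ndarray


def init_params(
    feature_dim: int,
    head: str = "survival",
    attention_dim: int = 128,
    hidden: tuple = (128, 64),
    dropout: float = 0.5,
    rng: np.random.Generator | None = None,
    dtype=np.float64,
) -> MILParams:
    """He-style random initialization of attention and head parameters."""
    if head not in ("survival", "binary"):
        raise ValueError("head must be 'survival' or 'binary'")
    rng = rng or np.random.default_rng()
    n_out = HORIZON if head == "survival" else 1
    V = (rng.standard_normal((attention_dim, feature_dim)) / np.sqrt(feature_dim)).astype(dtype)
    w = (rng.standard_normal(attention_dim) / np.sqrt(attention_dim)).astype(dtype)
    sizes = [feature_dim, *hidden, n_out]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(
            (rng.standard_normal((fan_out, fan_in)) * np.sqrt(2.0 / fan_in)).astype(dtype)
        )
        biases.append(np.zeros(fan_out, dtype=dtype))
    activation = "softplus" if head == "survival" else "sigmoid"
    return MILParams(AttentionParams(V, w), HeadParams(weights, biases, activation, dropout))


def _softmax(u: np.ndarray) -> np.ndarray:
    e = np.exp(u - u.max())
    return e / e.sum()


def _softplus(x: np.ndarray) -> np.ndarray:
    # stable: log(1 + e^x) = max(x, 0) + log1p(e^{-|x|})
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def attend_and_pool(bag, params: AttentionParams) -> SlideFeature:
    """Pool a feature bag into a slide feature via gated-free attention."""
    F = bag.features if isinstance(bag, FeatureBag) else np.asarray(bag)
    if F.ndim != 2 or F.shape[0] < 1:
        raise ValueError("bag must be a K x M matrix with K >= 1")
    if F.shape[1] != params.V.shape[1]:
        raise ValueError(
            f"feature dim {F.shape[1]} does not match attention dim {params.V.shape[1]}"
        )
    T = np.tanh(F @ params.V.T)  # (K, L)
    a = _softmax(T @ params.w)
    return SlideFeature(z=a @ F, attention=a)


def _head_forward(z, head: HeadParams, train: bool, rng):
    """Pre-activation output of the head; caches intermediates for backward."""
    h = z
    hs, masks = [z], []
    n_layers = len(head.weights)
    for i, (W, b) in enumerate(zip(head.weights, head.biases)):
        pre = W @ h + b
        if i < n_layers - 1:
            h = np.maximum(pre, 0.0)
            if train and head.dropout > 0:
                mask = (rng.random(h.shape) >= head.dropout) / (1.0 - head.dropout)
                h = h * mask
            else:
                mask = None
            hs.append(h)
            masks.append(mask)
        else:
            h = pre
    return h, (hs, masks)


def predict_hazards(z, params) -> np.ndarray:
    """60 positive monthly hazard masses for a slide feature.

    Accepts a :class:`SlideFeature` or raw vector, and either full
    :class:`MILParams` or bare :class:`HeadParams`.
    """
    head = params.head if isinstance(params, MILParams) else params
    if head.activation != "softplus":
        raise ValueError("survival hazards require the softplus head")
    zv = z.z if isinstance(z, SlideFeature) else np.asarray(z)
    out, _ = _head_forward(zv, head, train=False, rng=None)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite head activations")
    return _softplus(out)


def predict_binary_risk(z, params) -> float:
    """Five-year death probability in (0, 1) for a slide feature."""
    head = params.head if isinstance(params, MILParams) else params
    if head.activation != "sigmoid":
        raise ValueError("binary risk requires the logistic head")
    zv = z.z if isinstance(z, SlideFeature) else np.asarray(z)
    out, _ = _head_forward(zv, head, train=False, rng=None)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite head activations")
    # clip away from exact 0/1 so the open-interval contract survives
    # floating-point saturation of the logistic link
    p = 1.0 / (1.0 + np.exp(-float(out[0])))
    return float(np.clip(p, 1e-12, 1.0 - 1e-12))


def forward_bag(F: np.ndarray, params: MILParams, train: bool = False, rng=None):
    """Full forward pass on one bag.

    Returns ``(out, cache)`` where ``out`` is the hazard vector (survival
    head, after softplus) or the scalar logit (binary head, before the
    logistic link), and ``cache`` feeds :func:`backward_bag`.
    """
    att, head = params.attention, params.head
    T = np.tanh(F @ att.V.T)
    u = T @ att.w
    a = _softmax(u)
    z = a @ F
    pre, (hs, masks) = _head_forward(z, head, train=train, rng=rng)
    if head.activation == "softplus":
        out = _softplus(pre)
    else:
        out = pre
    cache = (F, T, a, z, pre, hs, masks, params)
    return out, cache


def backward_bag(dout: np.ndarray, cache) -> list:
    """Gradients for one bag, aligned with ``MILParams.arrays()``.

    ``dout`` is the loss gradient with respect to the hazard vector
    (survival head) or the output logit (binary head).
    """
    F, T, a, z, pre, hs, masks, params = cache
    head = params.head
    if head.activation == "softplus":
        dpre = np.asarray(dout) / (1.0 + np.exp(-pre))  # softplus' = sigmoid
    else:
        dpre = np.asarray(dout, dtype=pre.dtype).reshape(pre.shape)
    dWs = [None] * len(head.weights)
    dbs = [None] * len(head.biases)
    grad = dpre
    for i in range(len(head.weights) - 1, -1, -1):
        h_in = hs[i]
        dWs[i] = grad[:, None] * h_in[None, :]
        dbs[i] = grad
        if i > 0:
            grad = head.weights[i].T @ grad
            if masks[i - 1] is not None:
                grad = grad * masks[i - 1]
            grad = grad * (hs[i] > 0)
    dz = head.weights[0].T @ dbs[0]
    da = F @ dz
    du = a * (da - a @ da)
    dw = T.T @ du
    dA = (du[:, None] * params.attention.w[None, :]) * (1.0 - T * T)
    dV = dA.T @ F
    return [dV, dw, *dWs, *dbs]


def save_checkpoint(params: MILParams, path) -> None:
    """Write parameters (npz) with a JSON sidecar of the architecture."""
    path = Path(path)
    arrays = {"V": params.attention.V, "w": params.attention.w}
    for i, (W, b) in enumerate(zip(params.head.weights, params.head.biases)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    np.savez(path, **arrays)
    meta = {
        "activation": params.head.activation,
        "dropout": params.head.dropout,
        "n_layers": len(params.head.weights),
        "attention_dim": int(params.attention.V.shape[0]),
        "feature_dim": int(params.attention.V.shape[1]),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> MILParams:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    npz = np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path)
    att = AttentionParams(npz["V"], npz["w"])
    weights = [npz[f"W{i}"] for i in range(meta["n_layers"])]
    biases = [npz[f"b{i}"] for i in range(meta["n_layers"])]
    return MILParams(att, HeadParams(weights, biases, meta["activation"], meta["dropout"]))
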