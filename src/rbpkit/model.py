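"""GRU sequence classifier with a linear/batch-norm/leaky-ReLU discriminator.

The network is a stack of gated recurrent unit (GRU) layers followed by a
discriminator head that maps the final hidden state to a probability of the
positive (RNA-binding) class.  Each GRU layer computes, per time step, with
``cat = [h_{t-1}, x_t]``::

    z_t = sigmoid(W_z . cat + b_z)            (update gate)
    r_t = sigmoid(W_r . cat + b_r)            (reset gate)
    g_t = tanh(W . [r_t * h_{t-1}, x_t] + b)  (candidate state)
    h_t = (1 - z_t) * h_{t-1} + z_t * g_t

with ``h_0 = 0``.  The discriminator is linear -> batch normalization ->
leaky ReLU -> linear -> scalar score; the probability is its sigmoid.

Everything here is plain NumPy: forward, backpropagation through time, and
parameter containers.  Layer count 0 is legal and reduces the network to a
pure linear model on the (pooled) input vector.

Note on the candidate state: the reset gate multiplies the previous hidden
state *inside* the candidate's input concatenation (the standard GRU form);
the update-gate blend weights the candidate by ``z_t``.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class GRULayerParams:
    """Weights of one GRU layer acting on the concatenation [h_{t-1}, x_t]."""

    W_z: np.ndarray  # (H, H + D_in)
    W_r: np.ndarray
    W: np.ndarray
    b_z: np.ndarray  # (H,)
    b_r: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        H = self.b_z.shape[0]
        for name in ("W_z", "W_r", "W"):
            m = getattr(self, name)
            if m.shape != self.W_z.shape or m.shape[0] != H:
                raise ValueError(f"inconsistent GRU shapes: {name} is {m.shape}")
        for name in ("b_r", "b"):
            if getattr(self, name).shape != (H,):
                raise ValueError(f"bias {name} must have shape ({H},)")
        if self.W_z.shape[1] <= H:
            raise ValueError("weight width must exceed hidden width (needs D_in >= 1)")

    @property
    def hidden(self) -> int:
        return self.b_z.shape[0]

    @property
    def d_in(self) -> int:
        return self.W_z.shape[1] - self.hidden

    def names(self) -> tuple[str, ...]:
        return ("W_z", "W_r", "W", "b_z", "b_r", "b")


@dataclass
class DiscriminatorParams:
    """Linear -> batch-norm -> leaky ReLU -> linear head."""

    W1: np.ndarray  # (hidden, d_in)
    b1: np.ndarray
    gamma: np.ndarray  # batch-norm scale
    beta: np.ndarray  # batch-norm shift
    running_mean: np.ndarray
    running_var: np.ndarray
    W2: np.ndarray  # (1, hidden)
    b2: np.ndarray  # (1,)
    negative_slope: float = 0.01
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1

    def names(self) -> tuple[str, ...]:
        return ("W1", "b1", "gamma", "beta", "W2", "b2")


@dataclass
class ClassifierParams:
    """All learnable state of the classifier plus per-layer freeze flags."""

    layers: list[GRULayerParams]
    discriminator: DiscriminatorParams
    frozen_mask: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frozen_mask:
            self.frozen_mask = [False] * len(self.layers)
        if len(self.frozen_mask) != len(self.layers):
            raise ValueError("frozen_mask length must equal layer count")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def d_in(self) -> int:
        if self.layers:
            return self.layers[0].d_in
        return self.W1_in

    @property
    def W1_in(self) -> int:
        return self.discriminator.W1.shape[1]


def init_params(
    n_layers: int = 6,
    d_in: int = 16,
    hidden: int = 32,
    disc_hidden: int = 64,
    seed: int = 0,
) -> ClassifierParams:
    """Allocate parameters with Glorot-uniform weights and zero biases,
    reproducibly from ``seed``."""
    if d_in < 1 or hidden < 1 or disc_hidden < 1 or n_layers < 0:
        raise ValueError("widths must be positive and n_layers >= 0")
    rng = np.random.default_rng(seed)

    def glorot(shape: tuple[int, int]) -> np.ndarray:
        lim = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-lim, lim, size=shape)

    layers = []
    width = d_in
    for _ in range(n_layers):
        shape = (hidden, hidden + width)
        layers.append(
            GRULayerParams(
                W_z=glorot(shape), W_r=glorot(shape), W=glorot(shape),
                b_z=np.zeros(hidden), b_r=np.zeros(hidden), b=np.zeros(hidden),
            )
        )
        width = hidden
    disc = DiscriminatorParams(
        W1=glorot((disc_hidden, width)),
        b1=np.zeros(disc_hidden),
        gamma=np.ones(disc_hidden),
        beta=np.zeros(disc_hidden),
        running_mean=np.zeros(disc_hidden),
        running_var=np.ones(disc_hidden),
        W2=glorot((1, disc_hidden)),
        b2=np.zeros(1),
    )
    return ClassifierParams(layers, disc)


def copy_and_freeze(params: ClassifierParams, freeze_gru: bool = True) -> ClassifierParams:
    """Deep copy; when ``freeze_gru`` every GRU layer is flagged frozen so
    subsequent optimization leaves its weights bit-identical."""
    out = copy.deepcopy(params)
    out.frozen_mask = [freeze_gru] * out.n_layers
    return out


# --------------------------------------------------------------------------
# Forward
# --------------------------------------------------------------------------

def gru_cell(
    x_t: np.ndarray, h_prev: np.ndarray, params: GRULayerParams
) -> np.ndarray:
    """One GRU step for a batch: x_t (B, D_in), h_prev (B, H) -> h_t (B, H)."""
    x_t = np.atleast_2d(np.asarray(x_t, dtype=float))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=float))
    if x_t.shape[1] != params.d_in or h_prev.shape[1] != params.hidden:
        raise ValueError(
            f"width mismatch: x_t {x_t.shape}, h_prev {h_prev.shape}, "
            f"layer expects D_in={params.d_in}, H={params.hidden}"
        )
    cat = np.concatenate([h_prev, x_t], axis=1)
    z = sigmoid(cat @ params.W_z.T + params.b_z)
    r = sigmoid(cat @ params.W_r.T + params.b_r)
    cat_c = np.concatenate([r * h_prev, x_t], axis=1)
    g = np.tanh(cat_c @ params.W.T + params.b)
    return (1.0 - z) * h_prev + z * g


def _layer_forward(x: np.ndarray, p: GRULayerParams, cache: Optional[list] = None) -> np.ndarray:
    """Run one layer over a (B, T, D_in) sequence; returns (B, T, H)."""
    B, T, _ = x.shape
    H = p.hidden
    h = np.zeros((B, H))
    out = np.empty((B, T, H))
    for t in range(T):
        x_t = x[:, t, :]
        cat = np.concatenate([h, x_t], axis=1)
        z = sigmoid(cat @ p.W_z.T + p.b_z)
        r = sigmoid(cat @ p.W_r.T + p.b_r)
        cat_c = np.concatenate([r * h, x_t], axis=1)
        g = np.tanh(cat_c @ p.W.T + p.b)
        h_new = (1.0 - z) * h + z * g
        if cache is not None:
            cache.append((h, x_t, z, r, g, cat, cat_c))
        out[:, t, :] = h_new
        h = h_new
    return out


def _disc_forward(
    h: np.ndarray, d: DiscriminatorParams, mode: str, cache: Optional[dict] = None
) -> np.ndarray:
    """Discriminator head: (B, H) -> logits (B,).  Train mode uses batch
    moments and updates the running statistics; eval mode uses the stored
    running moments (a pure function of its inputs)."""
    a1 = h @ d.W1.T + d.b1
    if mode == "train":
        mu = a1.mean(axis=0)
        var = a1.var(axis=0)
        d.running_mean = (1 - d.bn_momentum) * d.running_mean + d.bn_momentum * mu
        n = a1.shape[0]
        unbiased = var * n / max(n - 1, 1)
        d.running_var = (1 - d.bn_momentum) * d.running_var + d.bn_momentum * unbiased
    else:
        mu, var = d.running_mean, d.running_var
    inv_std = 1.0 / np.sqrt(var + d.bn_eps)
    xhat = (a1 - mu) * inv_std
    bn = d.gamma * xhat + d.beta
    act = np.where(bn >= 0, bn, d.negative_slope * bn)
    logits = (act @ d.W2.T + d.b2).ravel()
    if cache is not None:
        cache.update(h=h, a1=a1, xhat=xhat, inv_std=inv_std, bn=bn, act=act, mode=mode)
    return logits


def forward(
    inputs: np.ndarray,
    params: ClassifierParams,
    mode: str = "eval",
    _cache: Optional[dict] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Score a batch of input sequences.

    ``inputs`` is (B, T, D) or (B, D) (treated as T=1) or (T, D) for a
    single protein in per-residue form — disambiguated by ``params.d_in``.
    Returns ``(logits, probabilities)``, each of shape (B,).
    """
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    x = np.asarray(inputs, dtype=float)
    if x.ndim == 1:
        x = x[None, None, :]
    elif x.ndim == 2:
        if x.shape[1] == params.d_in:
            x = x[:, None, :]  # batch of pooled vectors, T = 1
        else:
            x = x[None, :, :]  # single per-residue sequence
    if x.ndim != 3 or x.shape[2] != params.d_in:
        raise ValueError(f"input width {x.shape[-1]} != model d_in {params.d_in}")
    if x.shape[1] == 0:
        raise ValueError("sequence length T must be >= 1")

    layer_caches: list[list] = []
    for p in params.layers:
        cache: Optional[list] = [] if _cache is not None else None
        x = _layer_forward(x, p, cache)
        if _cache is not None:
            layer_caches.append(cache)
    h_last = x[:, -1, :]
    disc_cache: Optional[dict] = {} if _cache is not None else None
    logits = _disc_forward(h_last, params.discriminator, mode, disc_cache)
    if _cache is not None:
        _cache.update(layers=layer_caches, disc=disc_cache, T=x.shape[1])
    return logits, sigmoid(logits)


# --------------------------------------------------------------------------
# Backward (gradients for training)
# --------------------------------------------------------------------------

def zero_grads(params: ClassifierParams) -> dict:
    g = {
        "layers": [
            {n: np.zeros_like(getattr(p, n)) for n in p.names()} for p in params.layers
        ],
        "disc": {n: np.zeros_like(getattr(params.discriminator, n))
                 for n in params.discriminator.names()},
    }
    return g


def backward(
    dlogits: np.ndarray, params: ClassifierParams, cache: dict
) -> dict:
    """Backpropagate d(loss)/d(logits) through the head and the GRU stack.

    Returns gradients in the same nesting as :func:`zero_grads`.  Uses the
    caches produced by ``forward(..., _cache=...)``; train-mode batch-norm
    gradients include the batch-moment terms.
    """
    grads = zero_grads(params)
    d = params.discriminator
    dc = cache["disc"]
    B = dlogits.shape[0]

    # head: logits = act @ W2.T + b2
    dact = dlogits[:, None] * d.W2  # (B, hidden)
    grads["disc"]["W2"][:] = dlogits[None, :] @ dc["act"]
    grads["disc"]["b2"][:] = dlogits.sum()

    dbn = np.where(dc["bn"] >= 0, 1.0, d.negative_slope) * dact
    grads["disc"]["gamma"][:] = (dbn * dc["xhat"]).sum(axis=0)
    grads["disc"]["beta"][:] = dbn.sum(axis=0)
    dxhat = dbn * d.gamma
    if dc["mode"] == "train":
        inv_std = dc["inv_std"]
        xhat = dc["xhat"]
        da1 = (inv_std / B) * (
            B * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )
    else:
        da1 = dxhat * dc["inv_std"]
    grads["disc"]["W1"][:] = da1.T @ dc["h"]
    grads["disc"]["b1"][:] = da1.sum(axis=0)
    dh_last = da1 @ d.W1  # (B, H_last)

    # GRU stack, last layer first; gradient enters only at the final step of
    # the last layer, and flows into every step of lower layers via dx.
    T = cache["T"]
    dx_seq = None  # d(loss)/d(layer output sequence) for the layer below
    for li in range(params.n_layers - 1, -1, -1):
        p = params.layers[li]
        lcache = cache["layers"][li]
        g = grads["layers"][li]
        H = p.hidden
        if dx_seq is None:
            dout = [np.zeros_like(dh_last) for _ in range(T)]
            dout[T - 1] = dh_last
        else:
            dout = dx_seq
        dx_seq_lower = []
        dh_next = np.zeros_like(dout[0])  # carried gradient w.r.t. h_t
        for t in range(T - 1, -1, -1):
            h_prev, x_t, z, r, gcand, cat, cat_c = lcache[t]
            dh = dout[t] + dh_next
            dz = dh * (gcand - h_prev)
            dg = dh * z
            dh_prev = dh * (1.0 - z)

            da_c = dg * (1.0 - gcand**2)
            g["W"] += da_c.T @ cat_c
            g["b"] += da_c.sum(axis=0)
            dcat_c = da_c @ p.W
            dm, dx_c = dcat_c[:, :H], dcat_c[:, H:]
            dr = dm * h_prev
            dh_prev = dh_prev + dm * r

            da_z = dz * z * (1.0 - z)
            g["W_z"] += da_z.T @ cat
            g["b_z"] += da_z.sum(axis=0)
            dcat_z = da_z @ p.W_z

            da_r = dr * r * (1.0 - r)
            g["W_r"] += da_r.T @ cat
            g["b_r"] += da_r.sum(axis=0)
            dcat_r = da_r @ p.W_r

            dh_prev = dh_prev + dcat_z[:, :H] + dcat_r[:, :H]
            dx_t = dx_c + dcat_z[:, H:] + dcat_r[:, H:]
            dx_seq_lower.append(dx_t)
            dh_next = dh_prev
        dx_seq_lower.reverse()
        dx_seq = dx_seq_lower
    return grads


# --------------------------------------------------------------------------
# Checkpoints
# --------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(params: ClassifierParams, path: str | Path, meta: Optional[dict] = None) -> None:
    """Write a versioned archive of all parameter tensors plus metadata."""
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(params.layers):
        for n in layer.names():
            arrays[f"layer{i}.{n}"] = getattr(layer, n)
    d = params.discriminator
    for n in d.names() + ("running_mean", "running_var"):
        arrays[f"disc.{n}"] = getattr(d, n)
    config = {
        "version": CHECKPOINT_VERSION,
        "n_layers": params.n_layers,
        "frozen_mask": params.frozen_mask,
        "negative_slope": d.negative_slope,
        "bn_eps": d.bn_eps,
        "bn_momentum": d.bn_momentum,
        "meta": meta or {},
    }
    arrays["__config__"] = np.frombuffer(json.dumps(config).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[ClassifierParams, dict]:
    with np.load(path) as data:
        config = json.loads(bytes(data["__config__"]).decode())
        if config["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {config['version']}")
        layers = []
        for i in range(config["n_layers"]):
            kw = {n: data[f"layer{i}.{n}"] for n in ("W_z", "W_r", "W", "b_z", "b_r", "b")}
            layers.append(GRULayerParams(**kw))
        d = DiscriminatorParams(
            W1=data["disc.W1"], b1=data["disc.b1"],
            gamma=data["disc.gamma"], beta=data["disc.beta"],
            running_mean=data["disc.running_mean"], running_var=data["disc.running_var"],
            W2=data["disc.W2"], b2=data["disc.b2"],
            negative_slope=config["negative_slope"],
            bn_eps=config["bn_eps"], bn_momentum=config["bn_momentum"],
        )
    return ClassifierParams(layers, d, list(config["frozen_mask"])), config["meta"]
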