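"""Restricted Boltzmann machines and greedy layer-wise DBN pre-training.

A binary RBM defines a joint distribution over visible units v and hidden
units h,

    P(v, h) = exp(-E(v, h)) / Z,
    E(v, h) = - sum_i a_i v_i - sum_j b_j h_j - sum_ij v_i w_ij h_j,

with Z the partition function.  Training follows contrastive divergence
(CD-k): one gradient step on the difference between the data statistics
<v h> and the statistics of a k-step Gibbs reconstruction.  The
Gaussian-visible variant models standardised real-valued inputs (unit
variance), replacing the visible bias term by the quadratic
sum_i (v_i - a_i)^2 / 2.

A deep belief network (DBN) is a stack of RBMs trained greedily: each
layer's hidden activation probabilities become the next layer's data.  The
learned weights can seed the dense layers of the supervised network.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "RBMParams",
    "DBNStack",
    "init_rbm",
    "rbm_energy",
    "rbm_free_energy",
    "rbm_prob_brute",
    "hidden_probs",
    "cd_update",
    "train_rbm",
    "pretrain_dbn",
    "save_dbn",
    "load_dbn",
]

_BRUTE_LIMIT = 20  # exhaustive enumeration cap on n_visible + n_hidden


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass
class RBMParams:
    """Weights and biases of one RBM.

    ``W`` is n_visible x n_hidden; ``a`` the visible bias; ``b`` the hidden
    bias; ``visible_type`` either ``"binary"`` or ``"gaussian"``.
    """

    W: np.ndarray
    a: np.ndarray
    b: np.ndarray
    visible_type: str = "binary"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        nv, nh = self.W.shape
        if self.a.shape != (nv,) or self.b.shape != (nh,):
            raise ValueError(
                f"inconsistent shapes: W {self.W.shape}, a {self.a.shape}, b {self.b.shape}"
            )
        if self.visible_type not in ("binary", "gaussian"):
            raise ValueError(f"unknown visible_type {self.visible_type!r}")
        for arr in (self.W, self.a, self.b):
            if not np.all(np.isfinite(arr)):
                raise ValueError("RBM parameters must be finite")

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]


def init_rbm(n_visible: int, n_hidden: int, visible_type: str = "binary",
             rng: np.random.Generator | None = None, scale: float = 0.01) -> RBMParams:
    """Small-Gaussian weight init, zero biases."""
    rng = rng or np.random.default_rng(0)
    return RBMParams(
        W=rng.normal(0.0, scale, size=(n_visible, n_hidden)),
        a=np.zeros(n_visible),
        b=np.zeros(n_hidden),
        visible_type=visible_type,
    )


def rbm_energy(params: RBMParams, v: np.ndarray, h: np.ndarray) -> float:
    """Energy E(v, h) of one joint configuration."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape != (params.n_visible,) or h.shape != (params.n_hidden,):
        raise ValueError("v/h shape mismatch with RBM parameters")
    if params.visible_type == "binary":
        vis_term = float(params.a @ v)
    else:
        vis_term = -0.5 * float(((v - params.a) ** 2).sum())
    return -vis_term - float(params.b @ h) - float(v @ params.W @ h)


def rbm_free_energy(params: RBMParams, v: np.ndarray) -> np.ndarray:
    """Free energy F(v) = -log sum_h exp(-E(v,h)), rows of ``v`` batched."""
    v = np.atleast_2d(np.asarray(v, dtype=float))
    x = v @ params.W + params.b
    softplus = np.logaddexp(0.0, x).sum(axis=1)
    if params.visible_type == "binary":
        vis = v @ params.a
    else:
        vis = -0.5 * ((v - params.a) ** 2).sum(axis=1)
    return -(vis + softplus)


def rbm_prob_brute(params: RBMParams, v: np.ndarray) -> float:
    """Exact P(v) by enumerating all binary configurations.

    Only valid for binary-visible RBMs with at most 20 total units; this is
    the independent likelihood oracle for CD training, never a training
    path.
    """
    if params.visible_type != "binary":
        raise ValueError("exact enumeration implemented for binary RBMs only")
    nv, nh = params.n_visible, params.n_hidden
    if nv + nh > _BRUTE_LIMIT:
        raise ValueError(f"instance too large for enumeration ({nv + nh} > {_BRUTE_LIMIT})")
    v = np.asarray(v, dtype=float)
    num = 0.0
    Z = 0.0
    for vv in itertools.product((0.0, 1.0), repeat=nv):
        vv = np.array(vv)
        for hh in itertools.product((0.0, 1.0), repeat=nh):
            w = np.exp(-rbm_energy(params, vv, np.array(hh)))
            Z += w
            if np.array_equal(vv, v):
                num += w
    return num / Z


def hidden_probs(params: RBMParams, v: np.ndarray) -> np.ndarray:
    """P(h=1 | v) for a batch of visible rows."""
    return _sigmoid(np.atleast_2d(v) @ params.W + params.b)


def _visible_mean(params: RBMParams, h: np.ndarray) -> np.ndarray:
    x = h @ params.W.T + params.a
    return _sigmoid(x) if params.visible_type == "binary" else x


def cd_update(params: RBMParams, batch: np.ndarray, k: int = 1,
              lr: float = 0.01, rng: np.random.Generator | None = None) -> RBMParams:
    """One contrastive-divergence (CD-k) gradient step on a batch.

    Hidden states are sampled during the Gibbs chain; visible
    reconstructions use mean values (standard CD practice, lowers sampling
    noise).  Deterministic under a seeded ``rng``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if lr < 0:
        raise ValueError("lr must be >= 0")
    rng = rng or np.random.default_rng(0)
    v0 = np.atleast_2d(np.asarray(batch, dtype=float))
    if v0.shape[1] != params.n_visible:
        raise ValueError("batch width mismatch with n_visible")
    if params.visible_type == "binary" and not np.isin(v0, (0.0, 1.0)).all():
        raise ValueError("binary RBM requires 0/1 data")
    n = v0.shape[0]

    ph0 = hidden_probs(params, v0)
    h = (rng.random(ph0.shape) < ph0).astype(float)
    vk = v0
    for _ in range(k):
        vk = _visible_mean(params, h)
        phk = hidden_probs(params, vk)
        h = (rng.random(phk.shape) < phk).astype(float)
    phk = hidden_probs(params, vk)

    dW = (v0.T @ ph0 - vk.T @ phk) / n
    da = (v0 - vk).mean(axis=0)
    db = (ph0 - phk).mean(axis=0)
    return replace(params, W=params.W + lr * dW, a=params.a + lr * da,
                   b=params.b + lr * db)


def train_rbm(data: np.ndarray, n_hidden: int, visible_type: str = "binary",
              epochs: int = 10, lr: float = 0.01, k: int = 1,
              batch_size: int = 100, seed: int = 0) -> RBMParams:
    """Fit one RBM by minibatch CD-k with a seeded sampler."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        raise ValueError("empty training data")
    rng = np.random.default_rng(seed)
    params = init_rbm(data.shape[1], n_hidden, visible_type, rng)
    n = data.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            batch = data[order[start:start + batch_size]]
            params = cd_update(params, batch, k=k, lr=lr, rng=rng)
    return params


@dataclass
class DBNStack:
    """Greedily trained stack of RBMs (layer i's hidden feeds layer i+1)."""

    layers: list[RBMParams] = field(default_factory=list)

    def __post_init__(self) -> None:
        for lo, hi in zip(self.layers, self.layers[1:]):
            if lo.n_hidden != hi.n_visible:
                raise ValueError(
                    f"layer size mismatch: {lo.n_hidden} hidden feeding "
                    f"{hi.n_visible} visible"
                )

    @property
    def layer_sizes(self) -> list[int]:
        if not self.layers:
            return []
        return [self.layers[0].n_visible] + [l.n_hidden for l in self.layers]

    def transform(self, data: np.ndarray) -> np.ndarray:
        """Propagate hidden activation probabilities through every layer."""
        x = np.atleast_2d(np.asarray(data, dtype=float))
        for layer in self.layers:
            x = hidden_probs(layer, x)
        return x


def pretrain_dbn(layer_sizes, data: np.ndarray, epochs: int = 10,
                 lr: float = 0.01, seed: int = 0,
                 visible_type: str = "binary", batch_size: int = 100) -> DBNStack:
    """Greedy layer-wise pre-training.

    ``layer_sizes`` are the hidden sizes, e.g. ``(768, 256)`` for the
    co-binding modality.  Only the first RBM sees raw data (and carries
    ``visible_type``); deeper RBMs model the binary-probability activations
    and are always binary-visible.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        raise ValueError("empty training data")
    layers: list[RBMParams] = []
    rng = np.random.default_rng(seed)
    x = data
    for depth, nh in enumerate(layer_sizes):
        vt = visible_type if depth == 0 else "binary"
        rbm = train_rbm(x, nh, visible_type=vt, epochs=epochs, lr=lr,
                        batch_size=batch_size, seed=seed + depth)
        layers.append(rbm)
        # deeper RBMs are binary-visible: train them on sampled hidden
        # states, not activation probabilities
        ph = hidden_probs(rbm, x)
        x = (rng.random(ph.shape) < ph).astype(float)
    return DBNStack(layers=layers)


def save_dbn(stack: DBNStack, path: str | Path) -> None:
    """Persist a DBN as a portable .npz archive."""
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(stack.layers):
        arrays[f"W{i}"] = layer.W
        arrays[f"a{i}"] = layer.a
        arrays[f"b{i}"] = layer.b
        arrays[f"type{i}"] = np.array(layer.visible_type)
    np.savez(path, n_layers=np.array(len(stack.layers)), **arrays)


def load_dbn(path: str | Path) -> DBNStack:
    with np.load(path) as data:
        n = int(data["n_layers"])
        layers = [
            RBMParams(W=data[f"W{i}"], a=data[f"a{i}"], b=data[f"b{i}"],
                      visible_type=str(data[f"type{i}"]))
            for i in range(n)
        ]
    return DBNStack(layers=layers)
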