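"""The hybrid multimodal network: a CNN branch over one-hot sequence plus a
two-layer dense branch per non-sequence modality, merged into a shared
hidden layer with a single sigmoid output.

Architecture (defaults in :class:`NetConfig`):

* sequence: conv (102 filters x length 10, valid, ReLU) -> max-pool
  (window 3) -> flatten -> dense 128 -> ReLU -> dropout
* region type: dense 256 -> 128; co-binding: 768 -> 256; structure and
  motif scores: 128 -> 64 (each dense layer ReLU + dropout 0.5)
* merge: concatenate -> batch norm -> dense 128 -> ReLU -> dropout ->
  dense 1 -> sigmoid

Trained end-to-end by RMSprop on binary cross-entropy, batch size 100, at
most 20 epochs, early stopping on validation loss.  All randomness
(weight init, shuffling, dropout masks) flows from one seeded generator,
so equal seeds give bitwise-identical runs.  Dense branches can optionally
be initialised from greedy RBM pre-training (:mod:`rbpdeep.rbm`).

Everything here is plain numpy; the convolution, pooling, batch-norm and
RMSprop steps are implemented explicitly and are checked against naive
loop oracles in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .encoders import MODALITIES, FeatureBundle
from .rbm import pretrain_dbn

__all__ = [
    "NetConfig",
    "TrainedModel",
    "conv_forward",
    "build_model",
    "train",
    "predict",
    "stack_bundles",
    "MultimodalNet",
]

# Table of per-modality (first, second) dense-layer widths.
DEFAULT_HIDDEN_SIZES = {
    "region_type": (256, 128),
    "cobinding": (768, 256),
    "structure": (128, 64),
    "motif": (128, 64),
}


@dataclass
class NetConfig:
    """Architecture and training hyperparameters."""

    nb_filter: int = 102
    filter_length: int = 10
    pool_length: int = 3
    pooling: str = "global"  # "global" (max over positions) or "local" (window pool_length)
    cnn_dense: int = 128
    hidden_sizes: dict = field(default_factory=lambda: dict(DEFAULT_HIDDEN_SIZES))
    merge_hidden: int = 128
    dropout_p: float = 0.5
    max_epochs: int = 20
    batch_size: int = 100
    learning_rate: float = 0.003
    rho: float = 0.9
    patience: int = 3
    seed: int = 0
    use_pretraining: bool = False
    pretrain_epochs: int = 10
    pretrain_lr: float = 0.01
    use_batchnorm: bool = True
    modalities: tuple = MODALITIES

    def __post_init__(self) -> None:
        if self.nb_filter < 1:
            raise ValueError("nb_filter must be >= 1")
        if not (1 <= self.filter_length <= 101):
            raise ValueError("filter_length must be in [1, 101]")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must be in [0, 1)")
        unknown = set(self.modalities) - set(MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities {sorted(unknown)}")
        self.modalities = tuple(self.modalities)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Layer:
    """Minimal layer protocol: forward caches, backward fills grads."""

    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x, train: bool, rng: np.random.Generator):
        raise NotImplementedError

    def backward(self, g):
        raise NotImplementedError


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {"W": _glorot(rng, n_in, n_out, (n_in, n_out)),
                       "b": np.zeros(n_out)}

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g):
        self.grads = {"W": self._x.T @ g, "b": g.sum(axis=0)}
        return g @ self.params["W"].T


class ReLU(_Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Dropout(_Layer):
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, p: float) -> None:
        super().__init__()
        self.p = p

    def forward(self, x, train, rng):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class BatchNorm(_Layer):
    """Per-feature batch normalisation with running inference statistics."""

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.params = {"gamma": np.ones(n), "beta": np.zeros(n)}
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train, rng):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        self._train = train
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, g):
        self.grads = {"gamma": (g * self._xhat).sum(axis=0), "beta": g.sum(axis=0)}
        gx = g * self.params["gamma"]
        if not self._train:
            return gx / self._std
        n = g.shape[0]
        return (gx - gx.mean(axis=0) - self._xhat * (gx * self._xhat).mean(axis=0)) / self._std


class Conv1D(_Layer):
    """Valid cross-correlation of (n, 101, 4) one-hot input with
    (nb_filter, filter_length, 4) filters, channel-summed; output
    (n, L, nb_filter) with L = 101 - filter_length + 1."""

    def __init__(self, nb_filter: int, filter_length: int, rng: np.random.Generator) -> None:
        super().__init__()
        fan_in = filter_length * 4
        self.params = {
            "W": _glorot(rng, fan_in, nb_filter, (nb_filter, filter_length, 4)),
            "b": np.zeros(nb_filter),
        }
        self.filter_length = filter_length

    def forward(self, x, train, rng):
        if x.ndim != 3 or x.shape[2] != 4:
            raise ValueError(f"expected (n, L, 4) one-hot input, got {x.shape}")
        w = self.filter_length
        self._windows = np.lib.stride_tricks.sliding_window_view(x, w, axis=1)
        # windows: (n, L, 4, w) -> align with W (F, w, 4)
        out = np.tensordot(self._windows, self.params["W"], axes=([3, 2], [1, 2]))
        self._x_shape = x.shape
        return out + self.params["b"]

    def backward(self, g):
        # g: (n, L, F)
        dW = np.tensordot(g, self._windows, axes=([0, 1], [0, 1]))  # (F, 4, w)
        self.grads = {"W": dW.transpose(0, 2, 1), "b": g.sum(axis=(0, 1))}
        n, L, _ = g.shape
        dx = np.zeros(self._x_shape)
        W = self.params["W"]  # (F, w, 4)
        for j in range(self.filter_length):
            dx[:, j:j + L, :] += g @ W[:, j, :]
        return dx


class MaxPool1D(_Layer):
    """Non-overlapping max pooling over positions; remainder dropped.
    ``length=None`` pools globally over all positions."""

    def __init__(self, length: int | None) -> None:
        super().__init__()
        self.length = length

    def forward(self, x, train, rng):
        n, L, F = x.shape
        if self.length is None:
            self._arg = x.argmax(axis=1)
            self._shape = x.shape
            return x.max(axis=1)[:, None, :]
        p = self.length
        nw = L // p
        xt = x[:, : nw * p, :].reshape(n, nw, p, F)
        self._arg = xt.argmax(axis=2)
        self._shape = x.shape
        return xt.max(axis=2)

    def backward(self, g):
        n, L, F = self._shape
        dx = np.zeros(self._shape)
        if self.length is None:
            ni, fi = np.meshgrid(np.arange(n), np.arange(F), indexing="ij")
            dx[ni, self._arg, fi] = g[:, 0, :]
            return dx
        p = self.length
        nw = L // p
        ni, wi, fi = np.meshgrid(np.arange(n), np.arange(nw), np.arange(F),
                                 indexing="ij")
        dxt = dx[:, : nw * p, :].reshape(n, nw, p, F)
        dxt[ni, wi, self._arg, fi] = g
        return dx


class Flatten(_Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


def conv_forward(onehot: np.ndarray, filters: np.ndarray,
                 bias: np.ndarray | None = None) -> np.ndarray:
    """ReLU-activated valid cross-correlation of one one-hot sequence.

    ``onehot`` is (101, 4); ``filters`` is (nb_filter, filter_length, 4).
    Returns the (nb_filter, L) activation map, L = 101 - filter_length + 1.
    """
    onehot = np.asarray(onehot, dtype=float)
    filters = np.asarray(filters, dtype=float)
    if onehot.ndim != 2 or onehot.shape[1] != 4 or filters.shape[2] != 4:
        raise ValueError("channel mismatch: expected 4-channel one-hot and filters")
    if filters.shape[1] > onehot.shape[0]:
        raise ValueError("filter longer than sequence")
    w = filters.shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(onehot, w, axis=0)  # (L, 4, w)
    out = np.tensordot(windows, filters, axes=([2, 1], [1, 2]))  # (L, F)
    if bias is not None:
        out = out + bias
    return np.maximum(out, 0.0).T


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def stack_bundles(bundles: list[FeatureBundle]) -> dict[str, np.ndarray]:
    """Stack per-sample bundles into per-modality batch arrays."""
    return {
        "region_type": np.stack([b.region_type for b in bundles]),
        "cobinding": np.stack([b.cobinding for b in bundles]),
        "structure": np.stack([b.structure for b in bundles]),
        "motif": np.stack([b.motif_scores for b in bundles]),
        "sequence": np.stack([b.onehot for b in bundles]),
    }


class MultimodalNet:
    """The assembled network.  Use :func:`build_model` to construct."""

    def __init__(self, config: NetConfig, input_dims: dict[str, int]) -> None:
        self.config = config
        self.input_dims = dict(input_dims)
        self.rng = np.random.default_rng(config.seed)
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        self.scaler: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._build()

    # -- construction ------------------------------------------------------
    def _build(self) -> None:
        cfg = self.config
        rng = self.rng
        self.branches: dict[str, list[_Layer]] = {}
        merged_dim = 0

        def bn(width: int) -> list[_Layer]:
            # batch norm after every dense layer stabilises joint training
            # when branch scales differ wildly (3030-d binary vs 101-d real)
            return [BatchNorm(width)] if cfg.use_batchnorm else []

        for mod in cfg.modalities:
            if mod == "sequence":
                L = 101 - cfg.filter_length + 1
                pooled = 1 if cfg.pooling == "global" else L // cfg.pool_length
                flat = pooled * cfg.nb_filter
                layers: list[_Layer] = [
                    Conv1D(cfg.nb_filter, cfg.filter_length, rng),
                    ReLU(),
                    MaxPool1D(None if cfg.pooling == "global" else cfg.pool_length),
                    Flatten(),
                    Dense(flat, cfg.cnn_dense, rng),
                    *bn(cfg.cnn_dense),
                    ReLU(),
                    Dropout(cfg.dropout_p),
                ]
                merged_dim += cfg.cnn_dense
            else:
                h1, h2 = cfg.hidden_sizes[mod]
                d = self.input_dims[mod]
                layers = [
                    Dense(d, h1, rng), *bn(h1), ReLU(), Dropout(cfg.dropout_p),
                    Dense(h1, h2, rng), *bn(h2), ReLU(), Dropout(cfg.dropout_p),
                ]
                merged_dim += h2
            self.branches[mod] = layers
        self.merge: list[_Layer] = [
            *bn(merged_dim),
            Dense(merged_dim, cfg.merge_hidden, rng), ReLU(),
            Dropout(cfg.dropout_p),
            Dense(cfg.merge_hidden, 1, rng),
        ]

    def init_from_dbn(self, inputs: dict[str, np.ndarray]) -> None:
        """Greedy RBM pre-training of the dense branches.

        Binary RBMs for the binary modalities (region type, co-binding),
        Gaussian-visible RBMs for the real-valued ones (structure, motif,
        standardised).  Learned weights and hidden biases seed the two
        dense layers of each branch.
        """
        cfg = self.config
        for mod in cfg.modalities:
            if mod == "sequence":
                continue
            x = self._scale(mod, inputs[mod])
            vt = "binary" if mod in ("region_type", "cobinding") else "gaussian"
            stack = pretrain_dbn(cfg.hidden_sizes[mod], x,
                                 epochs=cfg.pretrain_epochs, lr=cfg.pretrain_lr,
                                 seed=cfg.seed, visible_type=vt,
                                 batch_size=cfg.batch_size)
            dense_layers = [l for l in self.branches[mod] if isinstance(l, Dense)]
            for dense, rbm in zip(dense_layers, stack.layers):
                dense.params["W"] = rbm.W.copy()
                dense.params["b"] = rbm.b.copy()

    # -- plumbing ----------------------------------------------------------
    def _all_layers(self) -> list[_Layer]:
        out: list[_Layer] = []
        for mod in self.config.modalities:
            out += self.branches[mod]
        return out + self.merge

    def fit_scaler(self, inputs: dict[str, np.ndarray]) -> None:
        """Store train-set standardisation for the real-valued motif scores."""
        x = inputs.get("motif")
        if x is not None:
            sd = x.std(axis=0)
            self.scaler["motif"] = (x.mean(axis=0), np.where(sd > 0, sd, 1.0))

    def _scale(self, mod: str, x: np.ndarray) -> np.ndarray:
        if mod in self.scaler:
            mu, sd = self.scaler[mod]
            return (x - mu) / sd
        return x

    def _check_inputs(self, inputs: dict[str, np.ndarray]) -> None:
        for mod in self.config.modalities:
            if mod not in inputs:
                raise ValueError(f"missing modality {mod!r}")
            got = inputs[mod].shape[1:]
            want = (101, 4) if mod == "sequence" else (self.input_dims[mod],)
            if got != want:
                raise ValueError(f"modality {mod!r}: expected shape {want}, got {got}")

    def forward_logits(self, inputs: dict[str, np.ndarray], train: bool = False) -> np.ndarray:
        self._check_inputs(inputs)
        outs = []
        for mod in self.config.modalities:
            x = self._scale(mod, inputs[mod])
            for layer in self.branches[mod]:
                x = layer.forward(x, train, self.rng)
            outs.append(x)
        self._split = np.cumsum([o.shape[1] for o in outs])[:-1]
        z = np.concatenate(outs, axis=1)
        for layer in self.merge:
            z = layer.forward(z, train, self.rng)
        return z[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits[:, None]
        for layer in reversed(self.merge):
            g = layer.backward(g)
        parts = np.split(g, self._split, axis=1)
        for mod, gp in zip(self.config.modalities, parts):
            for layer in reversed(self.branches[mod]):
                gp = layer.backward(gp)

    def predict_proba(self, inputs: dict[str, np.ndarray]) -> np.ndarray:
        z = self.forward_logits(inputs, train=False)
        return _sigmoid(z)

    @property
    def filters(self) -> np.ndarray:
        """Learned conv filters, (nb_filter, filter_length, 4)."""
        return self.branches["sequence"][0].params["W"]

    @property
    def conv_bias(self) -> np.ndarray:
        return self.branches["sequence"][0].params["b"]

    def conv_activations(self, onehot_batch: np.ndarray) -> np.ndarray:
        """Post-ReLU conv activation maps, (n, L, nb_filter)."""
        conv = self.branches["sequence"][0]
        out = conv.forward(np.asarray(onehot_batch, dtype=float), False, self.rng)
        return np.maximum(out, 0.0)

    # -- persistence -------------------------------------------------------
    def snapshot(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in layer.params.items()}
                for layer in self._all_layers()]

    def restore(self, snap: list[dict[str, np.ndarray]]) -> None:
        for layer, params in zip(self._all_layers(), snap):
            layer.params = {k: v.copy() for k, v in params.items()}

    def save(self, path: str | Path) -> None:
        arrays: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self._all_layers()):
            for k, v in layer.params.items():
                arrays[f"p{i}_{k}"] = v
            if isinstance(layer, BatchNorm):
                arrays[f"p{i}_running_mean"] = layer.running_mean
                arrays[f"p{i}_running_var"] = layer.running_var
        for mod, (mu, sd) in self.scaler.items():
            arrays[f"scaler_{mod}_mu"] = mu
            arrays[f"scaler_{mod}_sd"] = sd
        np.savez(path, **arrays)

    def load(self, path: str | Path) -> None:
        with np.load(path) as data:
            for i, layer in enumerate(self._all_layers()):
                for k in layer.params:
                    layer.params[k] = data[f"p{i}_{k}"]
                if isinstance(layer, BatchNorm):
                    layer.running_mean = data[f"p{i}_running_mean"]
                    layer.running_var = data[f"p{i}_running_var"]
            for mod in list(self.config.modalities):
                if f"scaler_{mod}_mu" in data:
                    self.scaler[mod] = (data[f"scaler_{mod}_mu"],
                                        data[f"scaler_{mod}_sd"])


TrainedModel = MultimodalNet  # a trained model is the net plus its history


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _bce_with_logits(z: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(np.logaddexp(0.0, z) - y * z))


class _RMSprop:
    """RMSprop: divide each gradient by a running RMS of its history."""

    def __init__(self, lr: float, rho: float, eps: float = 1e-8) -> None:
        self.lr, self.rho, self.eps = lr, rho, eps
        self.cache: dict[int, dict[str, np.ndarray]] = {}

    def step(self, layers: list[_Layer]) -> None:
        for i, layer in enumerate(layers):
            if not layer.grads:
                continue
            cache = self.cache.setdefault(i, {})
            for k, g in layer.grads.items():
                c = cache.setdefault(k, np.zeros_like(g))
                c *= self.rho
                c += (1.0 - self.rho) * g * g
                layer.params[k] -= self.lr * g / (np.sqrt(c) + self.eps)
            layer.grads = {}


def build_model(config: NetConfig, input_dims: dict[str, int] | None = None) -> MultimodalNet:
    """Construct an untrained network.

    ``input_dims`` gives the per-modality feature dimensions; defaults to
    the standard 505/3030/101/102 benchmark dimensions.
    """
    dims = {"region_type": 505, "cobinding": 3030, "structure": 101, "motif": 102}
    if input_dims:
        dims.update(input_dims)
    return MultimodalNet(config, dims)


def train(model: MultimodalNet, bundles, labels, val_bundles=None,
          val_labels=None, config: NetConfig | None = None) -> MultimodalNet:
    """Train by minibatch RMSprop on binary cross-entropy.

    Dropout is active only during training batches; validation loss is
    monitored each epoch and training stops once it fails to improve for
    ``patience`` consecutive epochs, restoring the best parameters.
    Fully reproducible for a fixed config seed.
    """
    cfg = config or model.config
    X = bundles if isinstance(bundles, dict) else stack_bundles(bundles)
    y = np.asarray(labels, dtype=float)
    n = y.shape[0]
    if X["sequence" if "sequence" in X else list(X)[0]].shape[0] != n:
        raise ValueError("number of bundles and labels differ")
    if len(np.unique(y)) < 2:
        warnings.warn("training labels contain a single class", stacklevel=2)

    have_val = val_bundles is not None and val_labels is not None and len(val_labels) > 0
    if have_val:
        Xv = val_bundles if isinstance(val_bundles, dict) else stack_bundles(val_bundles)
        yv = np.asarray(val_labels, dtype=float)
    else:
        warnings.warn("no validation set: early stopping disabled", stacklevel=2)

    model.fit_scaler(X)
    if cfg.use_pretraining:
        model.init_from_dbn(X)

    opt = _RMSprop(cfg.learning_rate, cfg.rho)
    layers = model._all_layers()
    best_val = np.inf
    best_snap = None
    stall = 0
    for _ in range(cfg.max_epochs):
        order = model.rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            batch = {m: X[m][sel] for m in cfg.modalities}
            yb = y[sel]
            z = model.forward_logits(batch, train=True)
            epoch_loss += _bce_with_logits(z, yb) * len(sel)
            model.backward((_sigmoid(z) - yb) / len(sel))
            opt.step(layers)
        model.history["train_loss"].append(epoch_loss / n)
        if have_val:
            zv = model.forward_logits({m: Xv[m] for m in cfg.modalities}, train=False)
            vloss = _bce_with_logits(zv, yv)
            model.history["val_loss"].append(vloss)
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_snap = model.snapshot()
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break
    if best_snap is not None:
        model.restore(best_snap)
    return model


def predict(model: MultimodalNet, bundles) -> np.ndarray:
    """Deterministic per-sample binding probabilities in [0, 1]."""
    X = bundles if isinstance(bundles, dict) else stack_bundles(bundles)
    return model.predict_proba({m: X[m] for m in model.config.modalities})
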