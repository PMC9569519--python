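"""Convolutional immunogenicity classifier for peptide-MHC pairs.

Architecture
------------
Two parallel branches process the one-hot peptide matrix (11 x 21) and the
one-hot MHC pseudo-sequence matrix (33 x 21).  Each branch applies two
consecutive position-wise convolutional layers (each kernel spans the full
21-wide one-hot axis, learning a residue embedding while preserving
sequence position), then three dense layers producing a flattened
256-dimensional branch vector; the second and third dense layers carry
identity-skip (residual) connections.  The two branch vectors are
concatenated with the scaled binding-affinity and TAP scalars and passed
through two fusion dense layers to a single sigmoid output: the predicted
probability that the peptide-MHC pair is immunogenic.  Hidden layers use
ReLU activations and dropout; batch normalization is available as an option.

At the dataset sizes this model is trained on (thousands, not hundreds of
thousands, of pairs), two choices matter greatly for generalization and are
on by default: *transparent initialization* -- the convolutions and the
first branch dense layer start as exact identity/passthrough maps, so the
network begins as a shallow well-conditioned model of the raw one-hot
features and deepens only as training demands -- and a *branch warm-up*
during which only the fusion head trains.

Training
--------
Class-weighted binary cross-entropy (weights w_c = (1/S_c)(T/2) from the
training-split class counts) minimized with Adam (initial lr 0.001,
cosine-annealed, decoupled weight decay) in minibatches of 64 for at most
200 epochs, under two concurrent early-stopping monitors: training loss
with patience 15 and validation loss with patience 20.  The weights of the
best validation-loss epoch are restored at the end.  The default model is a
small deep ensemble: three members trained with different initialization
and shuffling seeds whose probabilities are averaged.

The network, its backpropagation and the Adam optimizer are implemented
directly on numpy arrays, which keeps the model dependency-light, fully
deterministic on CPU for a fixed seed, and small enough to train in seconds
at the dataset sizes involved.
"""

from __future__ import annotations

import hashlib
import io
import json
import dataclasses
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .alphabet import Alphabet, MAX_PEPTIDE_LENGTH, PseudoSequenceTable
from .features import (ClassWeights, EmptyClassError, NormalizationConstants,
                       class_weights)

__all__ = [
    "ModelConfig", "TrainedModel", "build_model", "train", "predict",
    "save_model", "load_model", "alphabet_hash", "IncompatibleModelError",
    "ModelLoadError",
]


class IncompatibleModelError(ValueError):
    """Model was trained under a different alphabet / pseudo-sequence table."""


class ModelLoadError(IOError):
    """Model artifact is unreadable or corrupt."""


def alphabet_hash(alphabet: Alphabet, table: PseudoSequenceTable) -> str:
    """Checksum binding a model to its encoding scheme.

    Covers the alphabet string, the pseudo-sequence position list and every
    allele entry, so any change to the encoding invalidates saved models.
    """
    h = hashlib.sha256()
    h.update(alphabet.symbols.encode())
    h.update(",".join(map(str, table.positions)).encode())
    for allele in sorted(table.entries):
        h.update(f"{allele}={table.entries[allele]};".encode())
    return h.hexdigest()


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    The printed protocol constants (batch size 64, max 200 epochs, Adam lr
    0.001, patience 15 on training loss and 20 on validation loss, 256-dim
    branch vectors) are the defaults; convolution filter counts, kernel
    heights, fusion widths and the dropout rate are free choices exposed
    here.
    """

    conv_filters: tuple[int, int] = (21, 21)
    kernel_heights: tuple[int, int] = (1, 1)
    pool_size: int | None = None
    branch_dense_units: tuple[int, int, int] = (256, 256, 256)
    fusion_dense_units: tuple[int, int] = (128, 64)
    batch_size: int = 64
    max_epochs: int = 200
    learning_rate: float = 1e-3
    lr_cosine_period: int | None = 60
    lr_min: float = 1e-5
    weight_decay: float = 3e-2
    patience_train_loss: int = 15
    patience_val_loss: int = 20
    use_batch_norm: bool = False
    dropout_rate: float = 0.2
    branch_dropout_rate: float = 0.0
    branch_warmup_epochs: int = 10
    n_members: int = 3
    residual_dense: bool = True
    transparent_init: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.branch_dense_units[-1] != 256:
            raise ValueError("branch output must be 256-dimensional")
        for name in ("batch_size", "max_epochs", "patience_train_loss",
                     "patience_val_loss"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# Layers.  Each layer owns `params` and `grads` dicts of identically keyed
# arrays; forward caches what backward needs.

class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init_scale: float | None = None):
        scale = np.sqrt(2.0 / n_in) if init_scale is None else init_scale
        self.params = {
            "W": rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float64),
            "b": np.zeros(n_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, training):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class _Conv1D:
    """Convolution along the sequence axis of a (N, L, C) input, valid padding.

    With ``kernel == 1`` this is a position-wise (1 x C) convolution over the
    full channel width -- a learned residue embedding that preserves
    position.  ``identity_init`` starts such a layer as a channel
    passthrough (plus small noise on the surplus filters), so the branch
    initially forwards its one-hot input unchanged.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 identity_init: bool = False):
        self.kernel = kernel
        scale = np.sqrt(2.0 / (kernel * c_in))
        w = rng.normal(0.0, scale, size=(kernel * c_in, c_out))
        if identity_init and kernel == 1 and c_out >= c_in:
            w = np.zeros_like(w)
            w[:c_in, :c_in] = np.eye(c_in)
        self.params = {"W": w, "b": np.zeros(c_out)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, training):
        n, length, c = x.shape
        k = self.kernel
        # (N, L-k+1, C, k) -> (N, L-k+1, k*C) windows
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        cols = win.transpose(0, 1, 3, 2).reshape(n, length - k + 1, k * c)
        self._cols, self._in_shape = cols, x.shape
        return cols @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        n, n_out, _ = dout.shape
        k = self.kernel
        c = self._in_shape[2]
        kc = k * c
        self.grads["W"] = self._cols.reshape(-1, kc).T @ dout.reshape(-1, dout.shape[2])
        self.grads["b"] = dout.sum(axis=(0, 1))
        dcols = (dout @ self.params["W"].T).reshape(n, n_out, k, c)
        dx = np.zeros(self._in_shape)
        for i in range(k):
            dx[:, i:i + n_out, :] += dcols[:, :, i, :]
        return dx


class _BatchNorm:
    """Batch normalization over all axes but the last (per-feature/channel)."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(n_features), "beta": np.zeros(n_features)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def forward(self, x, training):
        shape = x.shape
        flat = x.reshape(-1, shape[-1])
        if training:
            mean = flat.mean(axis=0)
            var = flat.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (flat - mean) * self._inv_std
        out = self.params["gamma"] * self._xhat + self.params["beta"]
        self._shape = shape
        return out.reshape(shape)

    def backward(self, dout):
        flat = dout.reshape(-1, dout.shape[-1])
        m = flat.shape[0]
        self.grads["gamma"] = (flat * self._xhat).sum(axis=0)
        self.grads["beta"] = flat.sum(axis=0)
        dxhat = flat * self.params["gamma"]
        dx = (self._inv_std / m) * (
            m * dxhat - dxhat.sum(axis=0) - self._xhat * (dxhat * self._xhat).sum(axis=0)
        )
        return dx.reshape(self._shape)


class _ReLU:
    params: dict = {}
    grads: dict = {}

    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _Dropout:
    """Inverted dropout; identity at inference time."""

    params: dict = {}
    grads: dict = {}

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate, self.rng = rate, rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class _MaxPool1D:
    """Non-overlapping max pooling along the sequence axis of (N, L, C)."""

    params: dict = {}
    grads: dict = {}

    def __init__(self, size: int):
        self.size = size

    def forward(self, x, training):
        n, length, c = x.shape
        n_out = length // self.size
        trimmed = x[:, :n_out * self.size, :].reshape(n, n_out, self.size, c)
        self._argmax = trimmed.argmax(axis=2)
        self._in_shape = x.shape
        return trimmed.max(axis=2)

    def backward(self, dout):
        n, n_out, c = dout.shape
        dwin = np.zeros((n, n_out, self.size, c))
        ni, oi, ci = np.ogrid[:n, :n_out, :c]
        dwin[ni, oi, self._argmax, ci] = dout
        dx = np.zeros(self._in_shape)
        dx[:, :n_out * self.size, :] = dwin.reshape(n, n_out * self.size, c)
        return dx


class _Flatten:
    params: dict = {}
    grads: dict = {}

    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class _Residual:
    """Identity-skip wrapper: forward(x) = inner(x) + x (shapes must match)."""

    def __init__(self, inner: "_Sequential"):
        self.inner = inner

    @property
    def layers(self):
        return self.inner.layers

    def forward(self, x, training):
        return self.inner.forward(x, training) + x

    def backward(self, dout):
        return self.inner.backward(dout) + dout


class _Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class ImmunogenicityCNN:
    """The two-branch network; holds layers and wires the branch merge."""

    def __init__(self, config: ModelConfig, pep_rows: int = MAX_PEPTIDE_LENGTH,
                 mhc_rows: int = 33, n_symbols: int = 21):
        self.config = config
        self.pep_rows, self.mhc_rows, self.n_symbols = pep_rows, mhc_rows, n_symbols
        rng = np.random.default_rng(config.seed)
        self.pep_branch = self._make_branch(pep_rows, rng)
        self.mhc_branch = self._make_branch(mhc_rows, rng)
        n_fused_in = 2 * config.branch_dense_units[-1] + 2  # + ba_norm, tap_norm
        self.fusion = self._make_fusion(n_fused_in, rng)
        self._train_rng = rng

    def _make_branch(self, n_rows: int, rng) -> _Sequential:
        cfg = self.config
        layers: list = []
        c_in = self.n_symbols
        out_rows = n_rows
        for c_out, k in zip(cfg.conv_filters, cfg.kernel_heights):
            layers.append(_Conv1D(c_in, c_out, k, rng,
                                  identity_init=cfg.transparent_init))
            if cfg.use_batch_norm:
                layers.append(_BatchNorm(c_out))
            layers.append(_ReLU())
            c_in = c_out
            out_rows -= k - 1
        if cfg.pool_size:
            layers.append(_MaxPool1D(cfg.pool_size))
            out_rows //= cfg.pool_size
        layers.append(_Flatten())
        n_in = out_rows * c_in
        for i, width in enumerate(cfg.branch_dense_units):
            last = i == len(cfg.branch_dense_units) - 1
            dense = _Dense(n_in, width, rng)
            if cfg.transparent_init and i == 0 and width >= n_in:
                # start as an exact passthrough of the flattened input; the
                # surplus output units start silent and train from zero
                w = np.zeros_like(dense.params["W"])
                w[np.arange(n_in), np.arange(n_in)] = 1.0
                dense.params["W"] = w
            block: list = [dense]
            if cfg.use_batch_norm and not last:
                block.append(_BatchNorm(width))
            block.append(_ReLU())
            if cfg.branch_dropout_rate > 0 and not last:
                block.append(_Dropout(cfg.branch_dropout_rate, rng))
            # identity skip keeps the pinned three-dense stack trainable at
            # small n; only possible when the widths line up
            if cfg.residual_dense and width == n_in:
                if cfg.transparent_init:
                    # near-zero inner weights: the block starts as identity;
                    # no BN inside, it would blow up the tiny inner signal
                    block = [_Dense(n_in, width, rng, init_scale=0.0), _ReLU()]
                    if cfg.branch_dropout_rate > 0 and not last:
                        block.append(_Dropout(cfg.branch_dropout_rate, rng))
                layers.append(_Residual(_Sequential(block)))
            else:
                layers.extend(block)
            n_in = width
        return _Sequential(layers)

    def _make_fusion(self, n_in: int, rng) -> _Sequential:
        cfg = self.config
        layers: list = []
        for width in cfg.fusion_dense_units:
            layers.append(_Dense(n_in, width, rng))
            if cfg.use_batch_norm:
                layers.append(_BatchNorm(width))
            layers.append(_ReLU())
            if cfg.dropout_rate > 0:
                layers.append(_Dropout(cfg.dropout_rate, rng))
            n_in = width
        layers.append(_Dense(n_in, 1, rng))
        return _Sequential(layers)

    # -- forward / backward ------------------------------------------------
    def branch_outputs(self, pep, mhc, training=False):
        return (self.pep_branch.forward(pep, training),
                self.mhc_branch.forward(mhc, training))

    def forward(self, pep, mhc, scalars, training=False):
        p_out, m_out = self.branch_outputs(pep, mhc, training)
        self._n_branch = p_out.shape[1]
        fused = np.concatenate([p_out, m_out, scalars], axis=1)
        z = self.fusion.forward(fused, training)
        return _sigmoid(z[:, 0])

    def backward(self, dz):
        dfused = self.fusion.backward(dz[:, None])
        nb = self._n_branch
        self.pep_branch.backward(dfused[:, :nb])
        self.mhc_branch.backward(dfused[:, nb:2 * nb])

    # -- parameter plumbing ------------------------------------------------
    def _all_layers(self):
        def walk(layers):
            for layer in layers:
                if isinstance(layer, _Residual):
                    yield from walk(layer.inner.layers)
                else:
                    yield layer
        for seq in (self.pep_branch, self.mhc_branch, self.fusion):
            yield from walk(seq.layers)

    def parameters(self):
        """Flat dict of every parameter and batch-norm running statistic."""
        out = {}
        for i, layer in enumerate(self._all_layers()):
            for k, v in layer.params.items():
                out[f"layer{i}.{k}"] = v
            if isinstance(layer, _BatchNorm):
                out[f"layer{i}.running_mean"] = layer.running_mean
                out[f"layer{i}.running_var"] = layer.running_var
        return out

    def set_parameters(self, state: dict) -> None:
        for i, layer in enumerate(self._all_layers()):
            for k in layer.params:
                layer.params[k] = state[f"layer{i}.{k}"].copy()
            if isinstance(layer, _BatchNorm):
                layer.running_mean = state[f"layer{i}.running_mean"].copy()
                layer.running_var = state[f"layer{i}.running_var"].copy()

    def snapshot(self) -> dict:
        return {k: v.copy() for k, v in self.parameters().items()}


class _Adam:
    """Adam with decoupled weight decay on weight matrices (not biases/BN)."""

    def __init__(self, net: ImmunogenicityCNN, lr: float, weight_decay: float = 0.0,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.net, self.lr, self.weight_decay = net, lr, weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self):
        self.t += 1
        for i, layer in enumerate(self.net._all_layers()):
            for k, g in layer.grads.items():
                key = f"{i}.{k}"
                m = self.m.setdefault(key, np.zeros_like(g))
                v = self.v.setdefault(key, np.zeros_like(g))
                m[:] = self.beta1 * m + (1 - self.beta1) * g
                v[:] = self.beta2 * v + (1 - self.beta2) * g * g
                mhat = m / (1 - self.beta1 ** self.t)
                vhat = v / (1 - self.beta2 ** self.t)
                layer.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                if self.weight_decay and k == "W":
                    layer.params[k] -= self.lr * self.weight_decay * layer.params[k]


def _weighted_bce(p, y, w):
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(w * (y * np.log(p) + (1 - y) * np.log(1 - p))))


@dataclass
class TrainedModel:
    """A trained classifier bundled with everything needed to reuse it.

    ``networks`` holds the ensemble members (independently initialized and
    shuffled, identical architecture); the prediction is the mean of the
    member probabilities.  Also carries the training configuration, the
    min-max constants fitted on the training split (applied verbatim at
    prediction time), the encoding checksum, the class weights used, and
    per-member per-epoch loss histories.
    """

    networks: list[ImmunogenicityCNN]
    config: ModelConfig
    norm_constants: dict[str, NormalizationConstants]
    alphabet_checksum: str
    weights_used: ClassWeights | None = None
    history: dict[str, list[float]] = field(default_factory=dict)
    best_epoch: int | None = None

    @property
    def network(self) -> ImmunogenicityCNN:
        """The first ensemble member (the whole model when n_members=1)."""
        return self.networks[0]


def build_model(config: ModelConfig | None = None, mhc_rows: int = 33
                ) -> ImmunogenicityCNN:
    """Construct one untrained network (seeded, deterministic initialization)."""
    return ImmunogenicityCNN(config or ModelConfig(), mhc_rows=mhc_rows)


def _learning_rate(config: ModelConfig, epoch: int) -> float:
    """Cosine-annealed learning rate (constant when no period configured)."""
    if not config.lr_cosine_period:
        return config.learning_rate
    frac = min(epoch, config.lr_cosine_period) / config.lr_cosine_period
    return max(config.lr_min,
               config.learning_rate * 0.5 * (1.0 + np.cos(np.pi * frac)))


def _train_member(arrays: dict, config: ModelConfig, member_seed: int,
                  cw: ClassWeights | None) -> tuple[ImmunogenicityCNN,
                                                    dict[str, list[float]], int]:
    """One training run of the full early-stopping protocol.

    Minimizes class-weighted BCE with Adam; the two branches stay frozen for
    the first ``branch_warmup_epochs`` so the fusion head fits on the
    transparently initialized (near-raw) branch features before joint
    training.  Stops at the first of: training loss stalled for
    ``patience_train_loss`` epochs, validation loss stalled for
    ``patience_val_loss`` epochs, or ``max_epochs``; restores the best
    validation-loss weights.
    """
    split = np.asarray(arrays["split"])
    tr = split == "train"
    va = split == "validation"
    y_tr = np.asarray(arrays["label"], dtype=float)[tr]
    y_va = np.asarray(arrays["label"], dtype=float)[va]
    w_tr = cw.per_sample(y_tr) if cw else np.ones_like(y_tr)
    w_va = cw.per_sample(y_va) if cw else np.ones_like(y_va)
    pep_tr, mhc_tr, sc_tr = (arrays[k][tr] for k in ("peptide", "mhc", "scalars"))
    pep_va, mhc_va, sc_va = (arrays[k][va] for k in ("peptide", "mhc", "scalars"))

    member_config = dataclasses.replace(config, seed=member_seed)
    net = ImmunogenicityCNN(member_config, mhc_rows=arrays["mhc"].shape[1])
    opt = _Adam(net, config.learning_rate, config.weight_decay)
    rng = np.random.default_rng(member_seed + 1)
    branch_layers = [l for seq in (net.pep_branch, net.mhc_branch)
                     for l in _walk_layers(seq.layers)]

    n = len(y_tr)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_train = best_val = np.inf
    stall_train = stall_val = 0
    best_state, best_epoch = net.snapshot(), 0

    for epoch in range(config.max_epochs):
        opt.lr = _learning_rate(config, epoch)
        frozen = epoch < config.branch_warmup_epochs
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            yb, wb = y_tr[idx], w_tr[idx]
            p = net.forward(pep_tr[idx], mhc_tr[idx], sc_tr[idx], training=True)
            epoch_loss += _weighted_bce(p, yb, wb) * len(idx)
            dz = wb * (p - yb) / len(idx)
            net.backward(dz)
            if frozen:
                for layer in branch_layers:
                    for g in layer.grads.values():
                        g[:] = 0.0
            opt.step()
        train_loss = epoch_loss / n
        p_val = net.forward(pep_va, mhc_va, sc_va, training=False)
        val_loss = _weighted_bce(p_val, y_va, w_va)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)

        if val_loss < best_val:
            best_val, stall_val = val_loss, 0
            best_state, best_epoch = net.snapshot(), epoch
        else:
            stall_val += 1
        if train_loss < best_train:
            best_train, stall_train = train_loss, 0
        else:
            stall_train += 1
        if stall_train >= config.patience_train_loss:
            break
        if stall_val >= config.patience_val_loss:
            break

    net.set_parameters(best_state)
    return net, history, best_epoch


def _walk_layers(layers):
    for layer in layers:
        if isinstance(layer, _Residual):
            yield from _walk_layers(layer.inner.layers)
        else:
            yield layer


def train(
    arrays: dict,
    config: ModelConfig | None = None,
    norm_constants: dict[str, NormalizationConstants] | None = None,
    alphabet_checksum: str = "",
    use_class_weights: bool = True,
) -> TrainedModel:
    """Train the classifier ensemble on encoded arrays.

    ``arrays`` must contain ``peptide`` (N,11,21), ``mhc`` (N,P,21),
    ``scalars`` (N,2), ``label`` (N,) and ``split`` (N, strings); the train
    and validation splits are used here.  ``config.n_members`` independent
    networks are trained (seeds ``config.seed + m``), each under the full
    early-stopping protocol; the model's score is their mean probability.
    """
    config = config or ModelConfig()
    split = np.asarray(arrays["split"])
    tr = split == "train"
    if not (split == "validation").any():
        raise ValueError("training requires a non-empty validation split")
    y_tr = np.asarray(arrays["label"], dtype=float)[tr]
    if y_tr.sum() == 0 or (1 - y_tr).sum() == 0:
        raise EmptyClassError("training split must contain both classes")
    cw = class_weights(int(y_tr.sum()), int((1 - y_tr).sum())) \
        if use_class_weights else None

    networks, history, best_epoch = [], {}, None
    for m in range(config.n_members):
        net, member_history, member_best = _train_member(
            arrays, config, config.seed + m, cw)
        networks.append(net)
        for key, values in member_history.items():
            history[f"member{m}_{key}"] = values
        if m == 0:
            history.update(member_history)
            best_epoch = member_best

    return TrainedModel(
        networks=networks,
        config=config,
        norm_constants=norm_constants or {},
        alphabet_checksum=alphabet_checksum,
        weights_used=cw,
        history=history,
        best_epoch=best_epoch,
    )


def predict(model: TrainedModel, arrays: dict, alphabet_checksum: str | None = None,
            batch_size: int = 1024) -> np.ndarray:
    """Predict immunogenicity probabilities for encoded pairs, in input order.

    If ``alphabet_checksum`` is given it must match the model's stored
    checksum; scores are identical whether computed singly or batched.
    """
    if alphabet_checksum is not None and model.alphabet_checksum and \
            alphabet_checksum != model.alphabet_checksum:
        raise IncompatibleModelError(
            "encoding checksum mismatch: model was trained under a different "
            "alphabet or pseudo-sequence table"
        )
    pep, mhc, sc = arrays["peptide"], arrays["mhc"], arrays["scalars"]
    member_scores = []
    for net in model.networks:
        out = [
            net.forward(pep[i:i + batch_size], mhc[i:i + batch_size],
                        sc[i:i + batch_size], training=False)
            for i in range(0, len(pep), batch_size)
        ]
        member_scores.append(np.concatenate(out) if out else np.empty(0))
    return np.mean(member_scores, axis=0)


# ---------------------------------------------------------------------------
# Persistence: a single .npz bundle holding every weight array plus a JSON
# metadata blob (config, normalization constants, checksums).

_FORMAT_VERSION = 1


def save_model(model: TrainedModel, path: str | Path) -> None:
    state = {
        f"member{m}/{key}": value
        for m, net in enumerate(model.networks)
        for key, value in net.parameters().items()
    }
    weight_digest = hashlib.sha256()
    for key in sorted(state):
        weight_digest.update(np.ascontiguousarray(state[key]).tobytes())
    meta = {
        "format_version": _FORMAT_VERSION,
        "config": asdict(model.config),
        "n_members": len(model.networks),
        "mhc_rows": model.network.mhc_rows,
        "norm_constants": {
            k: {"x_min": c.x_min, "x_max": c.x_max, "transform": c.transform}
            for k, c in model.norm_constants.items()
        },
        "alphabet_checksum": model.alphabet_checksum,
        "weight_checksum": weight_digest.hexdigest(),
        "history": model.history,
        "best_epoch": model.best_epoch,
        "class_weights": (
            None if model.weights_used is None else {
                "w_pos": model.weights_used.w_pos,
                "w_neg": model.weights_used.w_neg,
                "s_pos": model.weights_used.s_pos,
                "s_neg": model.weights_used.s_neg,
            }
        ),
    }
    buf = io.BytesIO()
    np.savez_compressed(buf, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                        **state)
    Path(path).write_bytes(buf.getvalue())


def load_model(path: str | Path) -> TrainedModel:
    try:
        with np.load(Path(path)) as npz:
            data = {k: npz[k] for k in npz.files}
    except Exception as exc:
        raise ModelLoadError(f"cannot read model artifact {path}: {exc}") from exc
    if "_meta" not in data:
        raise ModelLoadError(f"{path}: missing metadata block")
    try:
        meta = json.loads(bytes(data.pop("_meta")).decode())
    except Exception as exc:
        raise ModelLoadError(f"{path}: corrupt metadata: {exc}") from exc
    if meta.get("format_version") != _FORMAT_VERSION:
        raise ModelLoadError(f"{path}: unsupported format version")
    digest = hashlib.sha256()
    for key in sorted(data):
        digest.update(np.ascontiguousarray(data[key]).tobytes())
    if digest.hexdigest() != meta["weight_checksum"]:
        raise ModelLoadError(
            f"{path}: weight checksum mismatch "
            f"(expected {meta['weight_checksum'][:12]}..., got {digest.hexdigest()[:12]}...)"
        )
    cfg_dict = dict(meta["config"])
    for key in ("conv_filters", "kernel_heights", "branch_dense_units",
                "fusion_dense_units"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = ModelConfig(**cfg_dict)
    networks = []
    for m in range(meta["n_members"]):
        net = ImmunogenicityCNN(config, mhc_rows=meta["mhc_rows"])
        prefix = f"member{m}/"
        net.set_parameters({k[len(prefix):]: v for k, v in data.items()
                            if k.startswith(prefix)})
        networks.append(net)
    norm = {
        k: NormalizationConstants(v["x_min"], v["x_max"], v["transform"])
        for k, v in meta["norm_constants"].items()
    }
    cw = None
    if meta.get("class_weights"):
        d = meta["class_weights"]
        cw = ClassWeights(d["w_pos"], d["w_neg"], d["s_pos"], d["s_neg"])
    return TrainedModel(
        networks=networks, config=config, norm_constants=norm,
        alphabet_checksum=meta["alphabet_checksum"], weights_used=cw,
        history=meta["history"], best_epoch=meta["best_epoch"],
    )
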