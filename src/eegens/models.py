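"""Compact EEG epoch classifiers and their training protocol.

Two convolutional families map a 2-s multi-channel epoch to the probability
of class 1:

* ``inception`` — a stack of inception modules (parallel convolutions of
  several kernel lengths plus a pooled 1×1 branch, concatenated), with a
  residual shortcut every three modules and global average pooling.  Depth
  (the number of modules) is the main capacity knob, explored over
  {2, 4, 6, 8, 10}.
* ``eegnet`` — temporal convolution shared across channels, a depthwise
  spatial convolution collapsing the channel axis, then a separable
  temporal convolution, with average pooling between blocks.

Either family can carry an adapted-dropout head (ADS): a 32-unit dense
layer followed by dropout, which is the stochastic element exploited by
Monte Carlo dropout at inference.

Training follows a fixed protocol: Adam at an initial learning rate of
0.005, up to 50 iterations (passes over the training set), early stopping
with patience 15 on validation loss, learning-rate halving with patience 5,
and checkpointing of the best-validation-loss weights.

Model widths default to a desk-scale setting (8 filters per branch) so that
training is feasible on one CPU; widths are configuration, not architecture.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _nn
from ._nn import (
    Adam,
    AvgPoolDown,
    Conv1d,
    Dense,
    Dropout,
    ELU,
    Flatten,
    GlobalAvgPool,
    MaxPool1dSame,
    ReLU,
    SeparableConv1d,
    SpatialDepthwiseConv,
    TemporalConv,
    bce_grad,
    bce_with_logits,
    sigmoid,
)
from .bands import BROADBAND
from .preprocess import EpochArray
from .synthdata import ConfigurationError

__all__ = [
    "ModelSpec",
    "TrainingConfig",
    "TrainedModel",
    "EpochDataset",
    "EpochClassifier",
    "build_model",
    "train",
    "predict_proba",
    "INCEPTION_DEPTHS",
]

INCEPTION_DEPTHS = (2, 4, 6, 8, 10)


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description for one classifier."""

    family: str = "inception"          # "inception" | "eegnet"
    depth: int = 4                     # inception modules
    width: int = 8                     # filters per branch / F1
    ads: bool = False                  # adapted-dropout head (dense 32 + dropout)
    dropout_rate: float = 0.5
    init_scheme: str = "glorot_uniform"
    seed: int = 0
    kernel_sizes: tuple[int, ...] = (9, 19, 39)

    def validate(self) -> None:
        if self.family not in ("inception", "eegnet"):
            raise ConfigurationError(f"unknown model family {self.family!r}")
        if self.family == "inception" and self.depth not in INCEPTION_DEPTHS:
            raise ConfigurationError(
                f"inception depth must be one of {INCEPTION_DEPTHS}"
            )
        if self.ads and not 0.0 < self.dropout_rate < 1.0:
            raise ConfigurationError("ads requires dropout_rate in (0, 1)")
        if self.init_scheme not in _nn.INIT_SCHEMES:
            raise ConfigurationError(f"unknown init scheme {self.init_scheme!r}")


@dataclass(frozen=True)
class TrainingConfig:
    max_iterations: int = 50
    early_stop_patience: int = 15
    lr_init: float = 0.005
    lr_patience: int = 5
    lr_factor: float = 0.5
    batch_size: int = 64
    seed: int = 0

    def validate(self) -> None:
        if self.lr_init <= 0:
            raise ConfigurationError("lr_init must be positive")
        if self.early_stop_patience < 1 or self.lr_patience < 1:
            raise ConfigurationError("patience values must be >= 1")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

class _InceptionModule:
    def __init__(self, c_in, width, kernels, scheme, rng):
        self.bottleneck = Conv1d(c_in, width, 1, scheme, rng) if c_in > 1 else None
        b_in = width if self.bottleneck else c_in
        self.convs = [Conv1d(b_in, width, k, scheme, rng) for k in kernels]
        self.pool = MaxPool1dSame(3)
        self.pool_conv = Conv1d(c_in, width, 1, scheme, rng)
        self.relu = ReLU()
        self.c_out = width * (len(kernels) + 1)
        self.width = width

    def layers(self):
        out = list(self.convs) + [self.pool_conv]
        if self.bottleneck:
            out.append(self.bottleneck)
        return out

    def forward(self, x, **kw):
        b = self.bottleneck.forward(x, **kw) if self.bottleneck else x
        parts = [c.forward(b, **kw) for c in self.convs]
        parts.append(self.pool_conv.forward(self.pool.forward(x, **kw), **kw))
        return self.relu.forward(np.concatenate(parts, axis=1), **kw)

    def backward(self, dy):
        dy = self.relu.backward(dy)
        w = self.width
        db = None
        for i, c in enumerate(self.convs):
            d = c.backward(dy[:, i * w:(i + 1) * w])
            db = d if db is None else db + d
        n = len(self.convs)
        dx_pool = self.pool.backward(self.pool_conv.backward(dy[:, n * w:(n + 1) * w]))
        dx = self.bottleneck.backward(db) if self.bottleneck else db
        return dx + dx_pool


class _Head:
    """Optional ADS block (dense 32 + dropout) plus the output unit."""

    def __init__(self, n_in, ads, dropout_rate, scheme, rng):
        self.seq = []
        if ads:
            self.seq += [Dense(n_in, 32, scheme, rng), ReLU(),
                         Dropout(dropout_rate, mc_active=True)]
            n_in = 32
        self.seq.append(Dense(n_in, 1, scheme, rng))

    def layers(self):
        return [l for l in self.seq if l.params]

    def forward(self, x, **kw):
        for l in self.seq:
            x = l.forward(x, **kw)
        return x[:, 0]

    def backward(self, dy):
        dy = dy[:, None]
        for l in reversed(self.seq):
            dy = l.backward(dy)
        return dy


class NeuralNet:
    """Shared surface of both families: forward, backward, weight access."""

    has_mc_dropout: bool = False
    #: Scalar input scale (set from the training set's global SD) so that
    #: microvolt-range signals enter the first layer at unit order while
    #: between-epoch amplitude differences — often the discriminant — are
    #: preserved.
    input_scale: float = 1.0

    def prepare(self, x):
        return np.asarray(x, dtype=_nn.DTYPE) / _nn.DTYPE(self.input_scale)

    def _param_layers(self):
        raise NotImplementedError

    def forward_logits(self, x, *, train=False, rng=None, mc=False):
        raise NotImplementedError

    def backward(self, dlogit):
        raise NotImplementedError

    @property
    def params(self):
        return [p for l in self._param_layers() for p in l.params]

    @property
    def grads(self):
        return [g for l in self._param_layers() for g in l.grads]

    @property
    def n_params(self):
        return sum(p.size for p in self.params)

    def get_weights(self):
        return [p.copy() for p in self.params]

    def set_weights(self, weights):
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w

    def weight_checksum(self) -> str:
        h = hashlib.sha256()
        for p in self.params:
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    def predict_proba(self, x, batch=1024):
        out = []
        for i in range(0, x.shape[0], batch):
            out.append(sigmoid(self.forward_logits(x[i:i + batch])))
        return np.concatenate(out) if out else np.empty(0)


class InceptionNet(NeuralNet):
    def __init__(self, spec: ModelSpec, n_channels: int, samples_per_epoch: int):
        rng = np.random.default_rng(spec.seed)
        kernels = [min(k, samples_per_epoch) for k in spec.kernel_sizes]
        self.modules: list[_InceptionModule] = []
        self.res_proj: dict[int, Conv1d] = {}
        self.res_relu: dict[int, ReLU] = {}
        self.seg_start: dict[int, int] = {}
        c_in = n_channels
        res_c = n_channels
        for i in range(spec.depth):
            m = _InceptionModule(c_in, spec.width, kernels, spec.init_scheme, rng)
            self.modules.append(m)
            c_in = m.c_out
            if (i + 1) % 3 == 0:
                self.res_proj[i] = Conv1d(res_c, c_in, 1, spec.init_scheme, rng)
                self.res_relu[i] = ReLU()
                self.seg_start[i] = i - 2
                res_c = c_in
        self.gap = GlobalAvgPool()
        self.head = _Head(c_in, spec.ads, spec.dropout_rate, spec.init_scheme, rng)
        self.has_mc_dropout = spec.ads

    def _param_layers(self):
        out = []
        for m in self.modules:
            out += m.layers()
        out += list(self.res_proj.values())
        out += self.head.layers()
        return out

    def forward_logits(self, x, *, train=False, rng=None, mc=False):
        kw = dict(train=train, rng=rng, mc=mc)
        x = self.prepare(x)
        res_in = x
        self._res_inputs = {}
        for i, m in enumerate(self.modules):
            x = m.forward(x, **kw)
            if i in self.res_proj:
                self._res_inputs[i] = res_in
                sc = self.res_proj[i].forward(res_in, **kw)
                x = self.res_relu[i].forward(x + sc, **kw)
                res_in = x
        x = self.gap.forward(x, **kw)
        return self.head.forward(x, **kw)

    def backward(self, dlogit):
        dy = self.head.backward(dlogit)
        dy = self.gap.backward(dy)
        pending: dict[int, np.ndarray] = {}
        for i in range(len(self.modules) - 1, -1, -1):
            if i in self.res_proj:
                dz = self.res_relu[i].backward(dy)
                pending[self.seg_start[i]] = self.res_proj[i].backward(dz)
                dy = dz
            dy = self.modules[i].backward(dy)
            if i in pending:
                dy = dy + pending.pop(i)
        return dy


class EEGNet(NeuralNet):
    def __init__(self, spec: ModelSpec, n_channels: int, samples_per_epoch: int):
        rng = np.random.default_rng(spec.seed)
        f1 = spec.width
        d_mult = 2
        f2 = f1 * d_mult
        k_temporal = max(5, min(samples_per_epoch // 4, 65)) | 1
        scheme = spec.init_scheme
        self.block1 = [
            TemporalConv(f1, k_temporal, scheme, rng),
            SpatialDepthwiseConv(f1, d_mult, n_channels, scheme, rng),
            ELU(),
            AvgPoolDown(4),
            Dropout(0.25),
        ]
        self.block2 = [
            SeparableConv1d(f2, f2, 9, scheme, rng),
            ELU(),
            AvgPoolDown(8),
            Dropout(0.25),
            Flatten(),
        ]
        t_out = (samples_per_epoch // 4) // 8
        if t_out < 1:
            raise ConfigurationError("epoch too short for the eegnet pooling chain")
        self.head = _Head(f2 * t_out, spec.ads, spec.dropout_rate, scheme, rng)
        self.has_mc_dropout = spec.ads

    def _param_layers(self):
        return ([l for l in self.block1 if l.params]
                + [l for l in self.block2 if l.params]
                + self.head.layers())

    def forward_logits(self, x, *, train=False, rng=None, mc=False):
        kw = dict(train=train, rng=rng, mc=mc)
        x = self.prepare(x)
        for l in self.block1 + self.block2:
            x = l.forward(x, **kw)
        return self.head.forward(x, **kw)

    def backward(self, dlogit):
        dy = self.head.backward(dlogit)
        for l in reversed(self.block1 + self.block2):
            dy = l.backward(dy)
        return dy


def build_model(spec: ModelSpec, n_channels: int, samples_per_epoch: int) -> NeuralNet:
    """Instantiate an untrained network with seeded initial weights."""
    spec.validate()
    if n_channels < 1 or samples_per_epoch < 1:
        raise ConfigurationError("input dimensions must be positive")
    cls = InceptionNet if spec.family == "inception" else EEGNet
    return cls(spec, n_channels, samples_per_epoch)


# ---------------------------------------------------------------------------
# Data plumbing
# ---------------------------------------------------------------------------

@dataclass
class EpochDataset:
    """Stacked epochs across subjects, the shape the trainer consumes."""

    X: np.ndarray                 # [n_epochs, n_channels, samples]
    y: np.ndarray                 # [n_epochs] in {0, 1}
    subject_ids: np.ndarray       # [n_epochs] subject of each epoch
    band: str = BROADBAND

    @classmethod
    def from_epoch_arrays(cls, arrays: Sequence[EpochArray]) -> "EpochDataset":
        if not arrays:
            raise ValueError("no epoch arrays supplied")
        X = np.concatenate([a.data for a in arrays], axis=0)
        y = np.concatenate([np.full(a.n_epochs, a.label) for a in arrays])
        sid = np.concatenate([np.full(a.n_epochs, a.subject_id, dtype=object)
                              for a in arrays])
        return cls(X=X, y=y.astype(int), subject_ids=sid, band=arrays[0].band)

    @property
    def n_epochs(self) -> int:
        return self.X.shape[0]

    @property
    def subject_labels(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s, lab in zip(self.subject_ids, self.y):
            out[str(s)] = int(lab)
        return out


def _as_dataset(data) -> EpochDataset:
    if isinstance(data, EpochDataset):
        return data
    if isinstance(data, EpochArray):
        return EpochDataset.from_epoch_arrays([data])
    return EpochDataset.from_epoch_arrays(list(data))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """Fit result: best-checkpoint weights plus the training trace.

    Behaves as the results object of the fit: it can score new epochs
    (:meth:`predict_proba`), report its configuration and training history
    (:meth:`summary`), and be handed to the ensemble builders.
    """

    spec: ModelSpec
    weights: list[np.ndarray]
    best_val_loss: float
    history: dict[str, list[float]]
    n_channels: int
    samples_per_epoch: int
    band: str = BROADBAND
    stopped_at: int = 0
    input_scale: float = 1.0

    _net: NeuralNet | None = field(default=None, repr=False, compare=False)

    def network(self) -> NeuralNet:
        if self._net is None:
            self._net = build_model(self.spec, self.n_channels, self.samples_per_epoch)
            self._net.set_weights(self.weights)
            self._net.input_scale = self.input_scale
        return self._net

    def predict_proba(self, epochs) -> np.ndarray:
        ds = _as_dataset(epochs)
        if ds.X.shape[1] != self.n_channels or ds.X.shape[2] != self.samples_per_epoch:
            raise ValueError(
                f"epoch dims {ds.X.shape[1:]} do not match the trained model "
                f"({self.n_channels}, {self.samples_per_epoch})"
            )
        return self.network().predict_proba(ds.X)

    def summary(self) -> str:
        s = self.spec
        lines = [
            f"{s.family} classifier (depth={s.depth}, width={s.width}, "
            f"ads={s.ads}, init={s.init_scheme}, band={self.band})",
            f"  parameters:     {self.network().n_params}",
            f"  iterations run: {self.stopped_at}",
            f"  best val loss:  {self.best_val_loss:.4f}",
        ]
        return "\n".join(lines)


class _Plateau:
    """Counts iterations since the last strict improvement."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.stale = 0

    def update(self, value: float) -> bool:
        """Returns True when ``value`` improved on the best seen."""
        if value < self.best:
            self.best = value
            self.stale = 0
            return True
        self.stale += 1
        return False

    @property
    def triggered(self) -> bool:
        return self.stale >= self.patience


def _batched_loss(net, X, y, batch=1024) -> float:
    total = 0.0
    for i in range(0, X.shape[0], batch):
        z = net.forward_logits(X[i:i + batch])
        total += bce_with_logits(z, y[i:i + batch]) * (min(i + batch, X.shape[0]) - i)
    return total / X.shape[0]


def train(net: NeuralNet, train_data, val_data,
          cfg: TrainingConfig = TrainingConfig(), *,
          spec: ModelSpec | None = None, band: str = BROADBAND) -> TrainedModel:
    """Fit ``net`` and return the best-validation-loss checkpoint.

    One "iteration" is one pass over the training set.  Validation loss is
    evaluated after every iteration; the weights achieving the minimum are
    checkpointed and returned, regardless of where training stops.
    """
    cfg.validate()
    tr, va = _as_dataset(train_data), _as_dataset(val_data)
    if tr.n_epochs == 0 or va.n_epochs == 0:
        raise ValueError("training and validation sets must be non-empty")
    if len(np.unique(tr.y)) < 2:
        raise ValueError("training labels contain a single class")
    if tr.X.shape[1:] != va.X.shape[1:]:
        raise ValueError("train/validation epoch dimensions differ")

    scale = float(tr.X.std())
    net.input_scale = scale if scale > 0 else 1.0
    rng = np.random.default_rng(cfg.seed)
    lr = cfg.lr_init
    opt = Adam(net.params, lr=lr)
    stopper = _Plateau(cfg.early_stop_patience)
    lr_tracker = _Plateau(cfg.lr_patience)
    best_weights = net.get_weights()
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "lr": []}
    n = tr.n_epochs
    stopped_at = 0

    for it in range(1, cfg.max_iterations + 1):
        perm = rng.permutation(n)
        batch_losses = []
        for i in range(0, n, cfg.batch_size):
            idx = perm[i:i + cfg.batch_size]
            xb, yb = tr.X[idx], tr.y[idx]
            z = net.forward_logits(xb, train=True, rng=rng)
            batch_losses.append(bce_with_logits(z, yb))
            net.backward(bce_grad(z, yb))
            opt.step(net.grads)
        val_loss = _batched_loss(net, va.X, va.y)
        history["train_loss"].append(float(np.mean(batch_losses)))
        history["val_loss"].append(val_loss)
        history["lr"].append(lr)
        stopped_at = it

        if stopper.update(val_loss):
            best_weights = net.get_weights()
        lr_tracker.update(val_loss)
        if lr_tracker.triggered:
            lr *= cfg.lr_factor
            opt.lr = lr
            lr_tracker.stale = 0
        if stopper.triggered:
            break

    net.set_weights(best_weights)
    model_spec = spec if spec is not None else getattr(net, "spec", None)
    return TrainedModel(
        spec=model_spec,
        weights=best_weights,
        best_val_loss=float(stopper.best),
        history=history,
        n_channels=tr.X.shape[1],
        samples_per_epoch=tr.X.shape[2],
        band=band,
        stopped_at=stopped_at,
        input_scale=net.input_scale,
        _net=net,
    )


def predict_proba(trained: TrainedModel, epochs) -> np.ndarray:
    """One class-1 probability per epoch; deterministic (dropout disabled)."""
    return trained.predict_proba(epochs)


class EpochClassifier:
    """Model-style front end: configure once, ``fit`` returns the results.

    ``EpochClassifier(spec).fit(train, val, cfg)`` builds the network from
    the data dimensions, runs the training protocol and returns a
    :class:`TrainedModel`.
    """

    def __init__(self, spec: ModelSpec = ModelSpec(), band: str = BROADBAND):
        spec.validate()
        self.spec = spec
        self.band = band

    def fit(self, train_data, val_data,
            cfg: TrainingConfig = TrainingConfig()) -> TrainedModel:
        tr = _as_dataset(train_data)
        net = build_model(self.spec, tr.X.shape[1], tr.X.shape[2])
        return train(net, tr, _as_dataset(val_data), cfg,
                     spec=self.spec, band=self.band)

    def with_seed(self, seed: int, init_scheme: str | None = None) -> "EpochClassifier":
        spec = replace(self.spec, seed=seed,
                       **({"init_scheme": init_scheme} if init_scheme else {}))
        return EpochClassifier(spec, band=self.band)
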