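"""12-layer residual CNN for spectral-image traceability, plus metrics.

A compact NumPy implementation of the residual classifier used on
synchronous correlation-spectroscopy images: a stem convolution with
batch normalisation and ReLU, three identity blocks and two
downsampling convolution blocks (each block two 3x3 convolutions with
an additive skip connection, y = F(x, W) + x), global average pooling
and a dense softmax head.

Layer counting rule (audited by :meth:`ResNet12.layer_audit`): the
stem convolution (1) + 5 residual blocks x 2 convolutions (10) + the
dense output layer (1) = 12 weight layers.  The 1x1 projection
convolutions that reshape the skip path in the two downsampling
blocks carry parameters but are not counted, following the usual
depth-naming convention.

Training is plain mini-batch SGD with L2 weight decay; convolutions
run as im2col + matrix multiplication so everything stays in BLAS.
All randomness flows from a single seed, so runs are reproducible on
one machine.

The module also houses the one-vs-rest confusion-matrix metrics
(accuracy, precision, sensitivity, specificity) and the exponential
moving-average curve smoothing used for training-curve display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "ResNetConfig",
    "TrainingCurves",
    "ResNet12",
    "build_resnet12",
    "train",
    "evaluate",
    "metrics",
    "smooth_curve",
]

_DTYPE = np.float32


# ---------------------------------------------------------------------------
# Confusion matrix and evaluation metrics


@dataclass
class ConfusionMatrix:
    """K x K integer counts; rows = true class, columns = predicted."""

    counts: np.ndarray
    classes: list[str] | None = None

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            if not np.all(c == np.round(c)) or np.any(c < 0):
                raise ValueError("confusion matrix entries must be non-negative integers")
            c = c.astype(int)
        self.counts = c
        if self.classes is not None and len(self.classes) != c.shape[0]:
            raise ValueError("class name count does not match matrix size")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        names = self.classes or [str(i) for i in range(self.n_classes)]
        return pd.DataFrame(self.counts, index=names, columns=names)


def metrics(conf: ConfusionMatrix) -> dict:
    """One-vs-rest accuracy / precision / sensitivity / specificity.

    Per class c: TP = conf[c,c], FP = column sum - TP, FN = row sum - TP,
    TN = everything else; Acc = trace/total.  Macro values are unweighted
    class means over classes where the ratio is defined; 0/0 ratios are
    reported as NaN and listed in ``undefined``.
    """
    C = conf.counts
    total = conf.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    names = conf.classes or [str(i) for i in range(conf.n_classes)]
    tp = np.diag(C).astype(float)
    fp = C.sum(axis=0) - tp
    fn = C.sum(axis=1) - tp
    tn = total - tp - fp - fn

    def _ratio(num, den):
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        return r

    pre = _ratio(tp, tp + fp)
    sen = _ratio(tp, tp + fn)
    spe = _ratio(tn, tn + fp)
    per_class = pd.DataFrame(
        {"precision": pre, "sensitivity": sen, "specificity": spe}, index=names
    )
    undefined = [
        (names[i], m)
        for m, vals in (("precision", pre), ("sensitivity", sen), ("specificity", spe))
        for i in np.flatnonzero(np.isnan(vals))
    ]
    return {
        "accuracy": float(tp.sum() / total),
        "per_class": per_class,
        "macro_precision": float(np.nanmean(pre)),
        "macro_sensitivity": float(np.nanmean(sen)),
        "macro_specificity": float(np.nanmean(spe)),
        "undefined": undefined,
    }


def smooth_curve(values, alpha: float = 0.6) -> np.ndarray:
    """Exponential moving average used for training-curve display.

    out[0] = values[0]; out[i] = alpha * out[i-1] + (1 - alpha) * values[i].
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    v = np.asarray(values, dtype=float)
    out = np.empty_like(v)
    if v.size == 0:
        return out
    out[0] = v[0]
    for i in range(1, v.size):
        out[i] = alpha * out[i - 1] + (1 - alpha) * v[i]
    return out


# ---------------------------------------------------------------------------
# Layers


class _Conv:
    """3x3 (or 1x1) convolution via im2col + GEMM."""

    counted = True

    def __init__(self, cin, cout, k, stride, rng, name):
        self.stride = stride
        self.pad = k // 2
        self.k = k
        self.name = name
        fan_in = cin * k * k
        self.W = (rng.standard_normal((cout, cin, k, k)) * np.sqrt(2.0 / fan_in)).astype(_DTYPE)
        self.b = np.zeros(cout, dtype=_DTYPE)

    def params(self):
        return [("W", True), ("b", False)]  # (attr, apply weight decay)

    def forward(self, x, training):
        N, C, H, Wd = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]
        Ho, Wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(N * Ho * Wo, C * k * k)
        out = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        self._cache = (x.shape, cols, Ho, Wo)
        return np.ascontiguousarray(out.reshape(N, Ho, Wo, -1).transpose(0, 3, 1, 2))

    def backward(self, dout):
        (N, C, H, Wd), cols, Ho, Wo = self._cache
        k, s, p = self.k, self.stride, self.pad
        F = self.W.shape[0]
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, F)
        self.gW = (dmat.T @ cols).reshape(self.W.shape)
        self.gb = dmat.sum(axis=0)
        dcols = (dmat @ self.W.reshape(F, -1)).reshape(N, Ho, Wo, C, k, k)
        dxp = np.zeros((N, C, H + 2 * p, Wd + 2 * p), dtype=_DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * (Ho - 1) + 1 : s, j : j + s * (Wo - 1) + 1 : s] += (
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        self._cache = None
        return dxp[:, :, p : p + H, p : p + Wd] if p else dxp

    def n_params(self):
        return self.W.size + self.b.size


class _BatchNorm:
    counted = False

    def __init__(self, c, name, eps=1e-5, mom=0.9):
        self.gamma = np.ones(c, dtype=_DTYPE)
        self.beta = np.zeros(c, dtype=_DTYPE)
        self.rmean = np.zeros(c, dtype=_DTYPE)
        self.rvar = np.ones(c, dtype=_DTYPE)
        self.eps, self.mom, self.name = eps, mom, name

    def params(self):
        return [("gamma", False), ("beta", False)]

    def forward(self, x, training):
        ax = (0, 2, 3)
        if training:
            mu = x.mean(axis=ax)
            var = x.var(axis=ax)
            self.rmean = self.mom * self.rmean + (1 - self.mom) * mu
            self.rvar = self.mom * self.rvar + (1 - self.mom) * var
        else:
            mu, var = self.rmean, self.rvar
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        if training:
            self._cache = (xhat, inv, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout):
        xhat, inv, shape = self._cache
        N = shape[0] * shape[2] * shape[3]
        ax = (0, 2, 3)
        self.ggamma = (dout * xhat).sum(axis=ax)
        self.gbeta = dout.sum(axis=ax)
        g = self.gamma[None, :, None, None]
        dxhat = dout * g
        dx = (
            inv[None, :, None, None]
            / N
            * (
                N * dxhat
                - dxhat.sum(axis=ax)[None, :, None, None]
                - xhat * (dxhat * xhat).sum(axis=ax)[None, :, None, None]
            )
        )
        self._cache = None
        return dx.astype(_DTYPE)

    def n_params(self):
        return self.gamma.size + self.beta.size


class _ReLU:
    counted = False
    name = "relu"

    def params(self):
        return []

    def forward(self, x, training):
        mask = x > 0
        if training:
            self._cache = mask
        return x * mask

    def backward(self, dout):
        dx = dout * self._cache
        self._cache = None
        return dx


class _AvgPool:
    """Non-overlapping average pooling; the stem's dimensionality reducer.

    Averaging (rather than max) suits the smooth correlation-map
    images: it suppresses per-pixel noise instead of amplifying it.
    """

    counted = False

    def __init__(self, k=2):
        self.k = k
        self.name = f"avgpool{k}"

    def params(self):
        return []

    def forward(self, x, training):
        N, C, H, W = x.shape
        k = self.k
        if training:
            self._shape = x.shape
        return x.reshape(N, C, H // k, k, W // k, k).mean(axis=(3, 5))

    def backward(self, dout):
        N, C, H, W = self._shape
        k = self.k
        return (
            np.broadcast_to(
                dout[:, :, :, None, :, None] / (k * k), (N, C, H // k, k, W // k, k)
            )
            .reshape(N, C, H, W)
            .astype(_DTYPE)
        )


class _Block:
    """Residual unit y = F(x, W) + skip(x), F = conv-BN-ReLU-conv-BN."""

    def __init__(self, cin, cout, downsample, rng, name):
        s = 2 if downsample else 1
        self.conv1 = _Conv(cin, cout, 3, s, rng, f"{name}.conv1")
        self.bn1 = _BatchNorm(cout, f"{name}.bn1")
        self.relu1 = _ReLU()
        self.conv2 = _Conv(cout, cout, 3, 1, rng, f"{name}.conv2")
        self.bn2 = _BatchNorm(cout, f"{name}.bn2")
        self.proj = None
        self.proj_bn = None
        if downsample or cin != cout:
            self.proj = _Conv(cin, cout, 1, s, rng, f"{name}.proj")
            self.proj.counted = False  # projection shortcut: not a counted layer
            self.proj_bn = _BatchNorm(cout, f"{name}.proj_bn")
        self.name = name

    def layers(self):
        out = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2]
        if self.proj is not None:
            out += [self.proj, self.proj_bn]
        return out

    def forward(self, x, training):
        f = self.bn2.forward(
            self.conv2.forward(
                self.relu1.forward(self.bn1.forward(self.conv1.forward(x, training), training), training),
                training,
            ),
            training,
        )
        if self.proj is not None:
            skip = self.proj_bn.forward(self.proj.forward(x, training), training)
        else:
            skip = x
        out = f + skip
        if training:
            self._mask = out > 0
        return out * (out > 0)

    def backward(self, dout):
        dout = dout * self._mask
        self._mask = None
        dskip = dout
        if self.proj is not None:
            dskip = self.proj.backward(self.proj_bn.backward(dout))
        df = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(dout))))
        )
        return df + dskip


class _Dense:
    counted = True

    def __init__(self, cin, cout, rng, name):
        self.W = (rng.standard_normal((cin, cout)) * np.sqrt(2.0 / cin)).astype(_DTYPE)
        self.b = np.zeros(cout, dtype=_DTYPE)
        self.name = name

    def params(self):
        return [("W", True), ("b", False)]

    def forward(self, x, training):
        if training:
            self._cache = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.gW = self._cache.T @ dout
        self.gb = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._cache = None
        return dx

    def n_params(self):
        return self.W.size + self.b.size


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Network


@dataclass
class ResNetConfig:
    """Architecture and training hyperparameters of the 12-layer network."""

    n_classes: int = 5
    input_size: tuple = (224, 224)
    in_channels: int = 1
    stem_filters: int = 16
    #: (filters, downsample) per residual block; 3 identity + 2 downsampling
    blocks: tuple = ((16, False), (32, True), (32, False), (64, True), (64, False))
    learning_rate: float = 0.01
    weight_decay: float = 1e-4
    momentum: float = 0.9
    epochs: int = 50
    batch_size: int = 8
    seed: int = 0
    #: stem max-pool factor; None = auto (first residual block sees ~28 px)
    stem_pool: int | None = None
    #: stop once test accuracy first reaches 100 % (curves end at that epoch)
    stop_when_test_perfect: bool = True

    def __post_init__(self):
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning rate must be positive and weight decay non-negative")
        if self.stem_pool is None:
            # stride-2 stem + pool: high-resolution inputs are reduced so the
            # first residual block operates at roughly 28x28
            self.stem_pool = max(2, int(2 ** np.floor(np.log2(min(self.input_size) / 56))))
        # stem stride 2 + stem pool + two downsampling blocks
        down = 2 * self.stem_pool * int(np.prod([2 for _, d in self.blocks if d]))
        if min(self.input_size) < down:
            raise ValueError(
                f"input size {self.input_size} smaller than total downsampling factor {down}"
            )


class ResNet12:
    """Stem conv -> 3 identity + 2 downsampling residual blocks -> GAP -> softmax."""

    def __init__(self, config: ResNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.stem = _Conv(config.in_channels, config.stem_filters, 3, 2, rng, "stem")
        self.stem_bn = _BatchNorm(config.stem_filters, "stem_bn")
        self.stem_relu = _ReLU()
        self.pool = _AvgPool(config.stem_pool)
        self.blocks = []
        cin = config.stem_filters
        for i, (cout, down) in enumerate(config.blocks):
            kind = "down" if down else "id"
            self.blocks.append(_Block(cin, cout, down, rng, f"block{i + 1}_{kind}"))
            cin = cout
        self.head = _Dense(cin, config.n_classes, rng, "head")
        self._velocity = {}

    # -- plumbing ----------------------------------------------------------

    def _layers(self):
        out = [self.stem, self.stem_bn, self.stem_relu, self.pool]
        for b in self.blocks:
            out += b.layers()
        out.append(self.head)
        return out

    def layer_audit(self) -> pd.DataFrame:
        """Table of weight layers with the counting rule applied."""
        rows = [
            {"layer": l.name, "counted": l.counted, "n_params": l.n_params()}
            for l in self._layers()
            if isinstance(l, (_Conv, _Dense))
        ]
        return pd.DataFrame(rows)

    def n_counted_layers(self) -> int:
        return int(self.layer_audit()["counted"].sum())

    def n_parameters(self) -> int:
        return sum(l.n_params() for l in self._layers() if hasattr(l, "n_params"))

    # -- forward / backward ------------------------------------------------

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=_DTYPE)
        if x.ndim == 3:
            x = x[:, None, :, :]
        h = self.pool.forward(
            self.stem_relu.forward(self.stem_bn.forward(self.stem.forward(x, training), training), training),
            training,
        )
        for b in self.blocks:
            h = b.forward(h, training)
        self._gap_hw = h.shape[2] * h.shape[3]
        pooled = h.mean(axis=(2, 3))
        self._gap_shape = h.shape
        logits = self.head.forward(pooled, training)
        return logits

    def predict_proba(self, x, batch_size=16):
        x = np.asarray(x, dtype=_DTYPE)
        if x.ndim == 3:
            x = x[:, None, :, :]
        out = [softmax(self.forward(x[i : i + batch_size])) for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    def predict(self, x) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def _backward_from_logits(self, dlogits):
        dpooled = self.head.backward(dlogits)
        N, C, H, W = self._gap_shape
        dh = np.broadcast_to(dpooled[:, :, None, None] / (H * W), (N, C, H, W)).astype(_DTYPE)
        for b in reversed(self.blocks):
            dh = b.backward(dh)
        self.stem.backward(self.stem_bn.backward(self.stem_relu.backward(self.pool.backward(dh))))

    def _sgd_step(self):
        cfg = self.config
        for layer in self._layers():
            for attr, decay in layer.params():
                p = getattr(layer, attr)
                g = getattr(layer, "g" + attr)
                if decay and cfg.weight_decay:
                    g = g + cfg.weight_decay * p
                key = (id(layer), attr)
                if cfg.momentum:
                    v = self._velocity.get(key, 0.0)
                    v = cfg.momentum * v - cfg.learning_rate * g
                    self._velocity[key] = v
                    setattr(layer, attr, (p + v).astype(_DTYPE))
                else:
                    setattr(layer, attr, (p - cfg.learning_rate * g).astype(_DTYPE))


    # -- persistence --------------------------------------------------------

    _STATE_ATTRS = ("W", "b", "gamma", "beta", "rmean", "rvar")

    def save(self, path) -> None:
        """Checkpoint: parameter arrays plus the architecture config (JSON)."""
        import dataclasses
        import json

        state = {"config": json.dumps(dataclasses.asdict(self.config))}
        for i, layer in enumerate(self._layers()):
            for attr in self._STATE_ATTRS:
                if hasattr(layer, attr):
                    state[f"{i}.{attr}"] = getattr(layer, attr)
        np.savez(path, **state)

    @classmethod
    def load(cls, path) -> "ResNet12":
        import json

        with np.load(path, allow_pickle=False) as state:
            cfg = json.loads(str(state["config"]))
            for key in ("input_size", "blocks"):
                cfg[key] = tuple(tuple(b) if isinstance(b, list) else b for b in cfg[key]) \
                    if key == "blocks" else tuple(cfg[key])
            model = cls(ResNetConfig(**cfg))
            for i, layer in enumerate(model._layers()):
                for attr in cls._STATE_ATTRS:
                    if hasattr(layer, attr):
                        setattr(layer, attr, state[f"{i}.{attr}"])
        return model


def build_resnet12(config: ResNetConfig) -> ResNet12:
    """Instantiate the 12-layer residual network with seeded He initialisation."""
    return ResNet12(config)


@dataclass
class TrainingCurves:
    """Per-epoch accuracy and cross-entropy loss for train/test sets."""

    train_acc: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    test_acc: list = field(default_factory=list)
    test_loss: list = field(default_factory=list)
    smoothing: float = 0.6

    def smoothed(self, which: str) -> np.ndarray:
        return smooth_curve(getattr(self, which), self.smoothing)

    def to_frame(self) -> pd.DataFrame:
        d = {"epoch": np.arange(1, len(self.train_acc) + 1),
             "train_acc": self.train_acc, "train_loss": self.train_loss}
        if self.test_acc:
            d["test_acc"] = self.test_acc
            d["test_loss"] = self.test_loss
        return pd.DataFrame(d)


def _xent_and_acc(model, x, y, batch_size=16):
    p = model.predict_proba(x, batch_size=batch_size)
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(len(y)), y] + eps))
    return float(loss), float(np.mean(p.argmax(axis=1) == y))


def train(
    model: ResNet12,
    images: np.ndarray,
    labels: np.ndarray,
    test_images: np.ndarray | None = None,
    test_labels: np.ndarray | None = None,
) -> TrainingCurves:
    """Mini-batch SGD training with per-epoch curve recording.

    ``labels`` are integer class indices.  If a test set is supplied,
    test accuracy/loss are recorded each epoch; with
    ``stop_when_test_perfect`` the loop ends at the first epoch whose
    test accuracy is 100 %.
    """
    cfg = model.config
    y = np.asarray(labels)
    if y.min() < 0 or y.max() >= cfg.n_classes:
        raise ValueError("label outside [0, n_classes)")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least two classes")
    x = np.asarray(images, dtype=_DTYPE)
    if x.ndim == 3:
        x = x[:, None, :, :]
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(y)
    curves = TrainingCurves()
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward(xb, training=True)
            p = softmax(logits)
            eps = 1e-12
            loss = -np.mean(np.log(p[np.arange(len(yb)), yb] + eps))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/Inf training loss at epoch {epoch + 1}; try a lower learning rate"
                )
            ep_loss += loss * len(yb)
            ep_correct += int((p.argmax(axis=1) == yb).sum())
            dlogits = (p - np.eye(cfg.n_classes, dtype=_DTYPE)[yb]) / len(yb)
            model._backward_from_logits(dlogits.astype(_DTYPE))
            model._sgd_step()
        curves.train_loss.append(ep_loss / n)
        curves.train_acc.append(ep_correct / n)
        if test_images is not None:
            tl, ta = _xent_and_acc(model, test_images, np.asarray(test_labels))
            curves.test_loss.append(tl)
            curves.test_acc.append(ta)
            if cfg.stop_when_test_perfect and ta == 1.0:
                break
    return curves


def evaluate(model: ResNet12, images, labels, classes: list[str] | None = None) -> ConfusionMatrix:
    """Tally argmax predictions into a K x K confusion matrix."""
    y = np.asarray(labels)
    K = model.config.n_classes
    if y.min() < 0 or y.max() >= K:
        raise ValueError("label outside [0, n_classes)")
    pred = model.predict(images)
    counts = np.zeros((K, K), dtype=int)
    np.add.at(counts, (y, pred), 1)
    return ConfusionMatrix(counts, classes=classes)
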