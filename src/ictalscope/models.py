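"""Small neural classifiers for 5-s EEG segments.

Four architecture families, matched to the input modalities they can read:

* ``fcnn`` — two ReLU hidden layers with dropout, for any 1-D input;
* ``rnn_lstm`` — consecutive sample pairs fed to an LSTM (20 units by
  default), hidden outputs averaged over time, then a 2-way output layer;
* ``cnn1d`` — two convolution(stride 1)-maxpool(stride 2) blocks followed by
  two dense hidden layers with dropout;
* ``cnn2d`` — same topology with 2-D convolutions, for image inputs.

All nets end in a 2-node softmax (seizure / non-seizure). Training is plain
minibatch Adam on cross-entropy with a random 10% validation split and early
stopping on validation loss, with the best-validation parameters restored.
The layers, backpropagation and optimizer live here in numpy: the networks
are tiny, and a self-contained implementation keeps runs bit-reproducible
from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _kernels
from .transforms import pair_sequence

__all__ = [
    "ArchitectureSpec",
    "TrainingConfig",
    "ScoredSegment",
    "build_classifier",
    "train",
    "predict_proba",
    "SegmentClassifier",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ArchitectureSpec:
    """Declarative description of one classifier.

    ``hidden_sizes`` configures the fully connected hidden layers (the whole
    net for ``fcnn``, the dense head after the conv blocks for the CNNs).
    ``conv_blocks`` is a list of ``{"filters": int, "kernel": int, "pool": int}``.
    """

    family: str = "fcnn"
    hidden_sizes: tuple[int, ...] | None = None
    lstm_units: int = 20
    conv_blocks: tuple[dict, ...] | None = None
    dropout: float = 0.3
    n_outputs: int = 2

    def __post_init__(self) -> None:
        if self.family not in ("fcnn", "rnn_lstm", "cnn1d", "cnn2d"):
            raise ValueError(f"unknown family {self.family!r}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.hidden_sizes is None:
            self.hidden_sizes = (256, 64) if self.family == "fcnn" else (128, 64)
        if self.conv_blocks is None:
            k = 5 if self.family == "cnn1d" else 3
            self.conv_blocks = ({"filters": 32, "kernel": k, "pool": 2},
                                {"filters": 64, "kernel": k, "pool": 2})


@dataclass
class TrainingConfig:
    minibatch: int = 128
    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    val_fraction: float = 0.10
    patience_epochs: int = 3
    max_epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.minibatch < 1:
            raise ValueError("minibatch must be >= 1")


@dataclass
class ScoredSegment:
    """A segment reference plus its seizure probability."""

    segment: object
    p_seizure: float


# ---------------------------------------------------------------------------
# layers


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def init(self, rng: np.random.Generator) -> None:  # pragma: no cover - default
        pass

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class _Dense(_Layer):
    def __init__(self, n_in: int, n_out: int) -> None:
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.W = np.zeros((n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def init(self, rng: np.random.Generator) -> None:
        self.W[...] = rng.standard_normal(self.W.shape) * np.sqrt(2.0 / self.n_in)
        self.b[...] = 0.0

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class _ReLU(_Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _Dropout(_Layer):
    def __init__(self, p: float) -> None:
        super().__init__()
        self.p = p

    def forward(self, x, train, rng):
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class _Flatten(_Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class _Conv1D(_Layer):
    """Stride-1 convolution with symmetric zero padding (odd kernel)."""

    def __init__(self, c_in: int, c_out: int, k: int) -> None:
        super().__init__()
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.W = np.zeros((c_out, c_in, k))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def init(self, rng):
        fan_in = self.c_in * self.k
        self.W[...] = rng.standard_normal(self.W.shape) * np.sqrt(2.0 / fan_in)
        self.b[...] = 0.0

    def forward(self, x, train, rng):
        p = self.k // 2
        self._xp = np.ascontiguousarray(np.pad(x, ((0, 0), (0, 0), (p, p))))
        return _kernels.conv1d_forward(self._xp, self.W, self.b)

    def backward(self, dout):
        p = self.k // 2
        L = dout.shape[2]
        dW, db, dxp = _kernels.conv1d_backward(self._xp, self.W, np.ascontiguousarray(dout))
        self.grads[0][...] = dW
        self.grads[1][...] = db
        return dxp[:, :, p : p + L]


class _MaxPool1D(_Layer):
    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x, train, rng):
        B, C, L = x.shape
        self._L = L
        Lc = (L // self.pool) * self.pool
        xr = x[:, :, :Lc].reshape(B, C, -1, self.pool)
        self._idx = xr.argmax(axis=3)
        return np.take_along_axis(xr, self._idx[..., None], axis=3)[..., 0]

    def backward(self, dout):
        B, C, Lp = dout.shape
        dxr = np.zeros((B, C, Lp, self.pool))
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=3)
        dx = np.zeros((B, C, self._L))
        dx[:, :, : Lp * self.pool] = dxr.reshape(B, C, -1)
        return dx


class _Conv2D(_Layer):
    def __init__(self, c_in: int, c_out: int, k: int) -> None:
        super().__init__()
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.W = np.zeros((c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def init(self, rng):
        fan_in = self.c_in * self.k * self.k
        self.W[...] = rng.standard_normal(self.W.shape) * np.sqrt(2.0 / fan_in)
        self.b[...] = 0.0

    def forward(self, x, train, rng):
        p = self.k // 2
        self._xp = np.ascontiguousarray(np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))))
        return _kernels.conv2d_forward(self._xp, self.W, self.b)

    def backward(self, dout):
        p = self.k // 2
        H, Wd = dout.shape[2], dout.shape[3]
        dW, db, dxp = _kernels.conv2d_backward(self._xp, self.W, np.ascontiguousarray(dout))
        self.grads[0][...] = dW
        self.grads[1][...] = db
        return dxp[:, :, p : p + H, p : p + Wd]


class _MaxPool2D(_Layer):
    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x, train, rng):
        B, C, H, W = x.shape
        self._HW = (H, W)
        q = self.pool
        Hc, Wc = (H // q) * q, (W // q) * q
        xr = x[:, :, :Hc, :Wc].reshape(B, C, Hc // q, q, Wc // q, q)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Hc // q, Wc // q, q * q)
        self._idx = xr.argmax(axis=4)
        return np.take_along_axis(xr, self._idx[..., None], axis=4)[..., 0]

    def backward(self, dout):
        B, C, Hp, Wp = dout.shape
        q = self.pool
        dxr = np.zeros((B, C, Hp, Wp, q * q))
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=4)
        dxr = dxr.reshape(B, C, Hp, Wp, q, q).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Hp * q, Wp * q)
        H, W = self._HW
        dx = np.zeros((B, C, H, W))
        dx[:, :, : Hp * q, : Wp * q] = dxr
        return dx


class _LSTMMean(_Layer):
    """LSTM over (B, T, D) inputs; output = hidden states averaged over time."""

    def __init__(self, d_in: int, units: int) -> None:
        super().__init__()
        self.d_in, self.units = d_in, units
        H = units
        self.Wx = np.zeros((d_in, 4 * H))
        self.Wh = np.zeros((H, 4 * H))
        self.b = np.zeros(4 * H)
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def init(self, rng):
        H = self.units
        self.Wx[...] = rng.standard_normal(self.Wx.shape) * np.sqrt(1.0 / self.d_in)
        self.Wh[...] = rng.standard_normal(self.Wh.shape) * np.sqrt(1.0 / H)
        self.b[...] = 0.0
        self.b[H : 2 * H] = 1.0  # forget-gate bias

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-np.clip(z, -50, 50)))

    def forward(self, x, train, rng):
        B, T, D = x.shape
        H = self.units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._x = x
        self._cache = []
        hsum = np.zeros((B, H))
        for t in range(T):
            z = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = self._sigmoid(z[:, :H])
            f = self._sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = self._sigmoid(z[:, 3 * H :])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            hc = np.tanh(c)
            h = o * hc
            hsum += h
            self._cache.append((i, f, g, o, c_prev, h_prev, hc))
        return hsum / T

    def backward(self, dmean):
        x = self._x
        B, T, D = x.shape
        H = self.units
        for gr in self.grads:
            gr[...] = 0.0
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        dh_step = dmean / T
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, h_prev, hc = self._cache[t]
            dh = dh_step + dh_next
            do = dh * hc
            dc = dh * o * (1 - hc * hc) + dc_next
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)], axis=1
            )
            self.grads[0] += x[:, t].T @ dz
            self.grads[1] += h_prev.T @ dz
            self.grads[2] += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return dx


# ---------------------------------------------------------------------------
# classifier


class SegmentClassifier:
    """A stack of layers plus the input adapter for its modality shape."""

    def __init__(self, spec: ArchitectureSpec, input_shape: tuple[int, ...]) -> None:
        self.spec = spec
        self.input_shape = tuple(int(s) for s in input_shape)
        self.layers = _build_layers(spec, self.input_shape)
        self._trained = False

    # -- plumbing

    def _adapt(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1:] != self.input_shape:
            raise ValueError(f"input shape {X.shape[1:]} does not match model shape {self.input_shape}")
        fam = self.spec.family
        if fam == "fcnn":
            return X.reshape(X.shape[0], -1)
        if fam == "cnn1d":
            return X[:, None, :]
        if fam == "cnn2d":
            return X[:, None, :, :]
        return np.stack([pair_sequence(row) for row in X])  # rnn: (B, T, 2)

    def init_params(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            layer.init(rng)

    def _forward(self, X: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        h = self._adapt(X)
        for layer in self.layers:
            h = layer.forward(h, train, rng)
        return h  # logits

    def _backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- inference

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) class probabilities; column 1 is p(seizure). Dropout off."""
        logits = self._forward(X, train=False)
        return _softmax(logits)

    def predict_p_seizure(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        out = [self.predict_proba(X[i : i + batch])[:, 1] for i in range(0, len(X), batch)]
        return np.concatenate(out) if out else np.empty(0)


def _build_layers(spec: ArchitectureSpec, input_shape: tuple[int, ...]) -> list[_Layer]:
    fam = spec.family
    layers: list[_Layer] = []
    if fam == "fcnn":
        if len(input_shape) != 1:
            raise ValueError("fcnn requires a 1-D input")
        n = input_shape[0]
        for h in spec.hidden_sizes:
            layers += [_Dense(n, h), _ReLU(), _Dropout(spec.dropout)]
            n = h
        layers.append(_Dense(n, spec.n_outputs))
    elif fam == "rnn_lstm":
        if len(input_shape) != 1 or input_shape[0] % 2:
            raise ValueError("rnn_lstm requires an even-length 1-D input")
        layers += [_LSTMMean(2, spec.lstm_units), _Dense(spec.lstm_units, spec.n_outputs)]
    elif fam == "cnn1d":
        if len(input_shape) != 1:
            raise ValueError("cnn1d requires a 1-D input")
        L, c = input_shape[0], 1
        for blk in spec.conv_blocks:
            layers += [_Conv1D(c, blk["filters"], blk["kernel"]), _ReLU(), _MaxPool1D(blk["pool"])]
            c = blk["filters"]
            L = L // blk["pool"]
        layers.append(_Flatten())
        n = c * L
        for h in spec.hidden_sizes:
            layers += [_Dense(n, h), _ReLU(), _Dropout(spec.dropout)]
            n = h
        layers.append(_Dense(n, spec.n_outputs))
    else:  # cnn2d
        if len(input_shape) != 2:
            raise ValueError("cnn2d requires a 2-D image input")
        H, W = input_shape
        c = 1
        for blk in spec.conv_blocks:
            layers += [_Conv2D(c, blk["filters"], blk["kernel"]), _ReLU(), _MaxPool2D(blk["pool"])]
            c = blk["filters"]
            H, W = H // blk["pool"], W // blk["pool"]
        layers.append(_Flatten())
        n = c * H * W
        for h in spec.hidden_sizes:
            layers += [_Dense(n, h), _ReLU(), _Dropout(spec.dropout)]
            n = h
        layers.append(_Dense(n, spec.n_outputs))
    return layers


def build_classifier(spec: ArchitectureSpec, input_shape: Sequence[int]) -> SegmentClassifier:
    """Construct an untrained classifier for the given modality shape."""
    return SegmentClassifier(spec, tuple(input_shape))


# ---------------------------------------------------------------------------
# training


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _xent(logits: np.ndarray, y: np.ndarray) -> float:
    p = _softmax(logits)
    return float(-np.mean(np.log(p[np.arange(len(y)), y] + 1e-12)))


class _Adam:
    def __init__(self, params: list[np.ndarray], cfg: TrainingConfig) -> None:
        self.cfg = cfg
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        c = self.cfg
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m[...] = c.beta1 * m + (1 - c.beta1) * g
            v[...] = c.beta2 * v + (1 - c.beta2) * g * g
            mhat = m / (1 - c.beta1**self.t)
            vhat = v / (1 - c.beta2**self.t)
            p -= c.lr * mhat / (np.sqrt(vhat) + 1e-8)


def train(
    classifier: SegmentClassifier,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainingConfig | None = None,
) -> tuple[SegmentClassifier, list[dict]]:
    """Fit with minibatch Adam, 10% validation split, early stopping.

    Returns the classifier (best-validation parameters restored) and a
    history list of ``{"epoch", "train_loss", "val_loss"}`` dicts, one per
    epoch actually run.
    """
    config = config or TrainingConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if len(X) != len(y):
        raise ValueError("inputs and labels differ in length")
    if np.unique(y).size < 2:
        raise ValueError("training data contains a single class")

    rng = np.random.default_rng(config.seed)
    classifier.init_params(rng)

    n = len(X)
    perm = rng.permutation(n)
    n_val = max(int(round(config.val_fraction * n)), 1)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if np.unique(y[tr_idx]).size < 2:  # degenerate split on tiny data
        tr_idx = perm
    Xtr, ytr, Xval, yval = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]

    opt = _Adam(classifier.parameters(), config)
    best_val = np.inf
    best_params = [p.copy() for p in classifier.parameters()]
    stall = 0
    history: list[dict] = []

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(Xtr))
        losses = []
        for i in range(0, len(Xtr), config.minibatch):
            idx = order[i : i + config.minibatch]
            xb, yb = Xtr[idx], ytr[idx]
            logits = classifier._forward(xb, train=True, rng=rng)
            p = _softmax(logits)
            losses.append(_xent(logits, yb))
            dlogits = p.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            classifier._backward(dlogits)
            opt.step(classifier.parameters(), classifier.gradients())

        val_logits = classifier._forward(Xval, train=False)
        val_loss = _xent(val_logits, yval)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": val_loss})

        if val_loss < best_val:
            best_val = val_loss
            best_params = [p.copy() for p in classifier.parameters()]
            stall = 0
        else:
            stall += 1
            if stall >= config.patience_epochs:
                break

    for p, bp in zip(classifier.parameters(), best_params):
        p[...] = bp
    classifier._trained = True
    return classifier, history


def save_model(classifier: SegmentClassifier, path, meta: dict | None = None) -> None:
    """Checkpoint: .npz of parameters plus a JSON sidecar with the spec."""
    import dataclasses
    import json
    from pathlib import Path

    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, *classifier.parameters())
    sidecar = {
        "spec": dataclasses.asdict(classifier.spec),
        "input_shape": list(classifier.input_shape),
        "meta": meta or {},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> SegmentClassifier:
    import json
    from pathlib import Path

    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec_d = dict(sidecar["spec"])
    spec_d["hidden_sizes"] = tuple(spec_d["hidden_sizes"])
    spec_d["conv_blocks"] = tuple(spec_d["conv_blocks"])
    clf = SegmentClassifier(ArchitectureSpec(**spec_d), tuple(sidecar["input_shape"]))
    with np.load(path) as z:
        arrays = [z[k] for k in z.files]
    for p, a in zip(clf.parameters(), arrays):
        p[...] = a
    clf._trained = True
    return clf


def predict_proba(classifier: SegmentClassifier, inputs: np.ndarray, segments: Sequence | None = None) -> list[ScoredSegment]:
    """Score a batch; order preserved. Dropout is disabled at inference."""
    X = np.asarray(inputs, dtype=np.float64)
    if X.shape[1:] != classifier.input_shape:
        raise ValueError(f"input shape {X.shape[1:]} does not match model shape {classifier.input_shape}")
    p = classifier.predict_p_seizure(X)
    refs = segments if segments is not None else [None] * len(p)
    return [ScoredSegment(segment=r, p_seizure=float(v)) for r, v in zip(refs, p)]
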