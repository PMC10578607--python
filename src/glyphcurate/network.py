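"""Small convolutional classifier, implemented directly in NumPy.

Architecture: conv(6 filters, 5x5, stride 1, ReLU) -> 2x2 max pool ->
conv(16 filters, 5x5, stride 1, ReLU) -> 2x2 max pool -> dense(128,
ReLU) -> dense(64, ReLU) -> K softmax outputs.  Convolutions are
unpadded; pooling uses stride 2.  Every layer but the output carries
50% inverted dropout during training.  Weights are He-normal except
the output layer, which is Glorot-uniform; training is Adam
(step size 0.005, beta1 0.9, beta2 0.999, eps 1e-8) on categorical
cross-entropy for 64 epochs with batch size 64.

Being pure NumPy with a seeded Generator, training is bitwise
reproducible: the same spec, data, and seed give identical parameters
and predictions.

Confidence of a prediction is the entropy (nats) of the softmax
output distribution; low entropy = high confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger("glyphcurate")


class ArchitectureError(ValueError):
    pass


@dataclass(frozen=True)
class NetSpec:
    """Hyperparameters of the classifier and its training protocol."""

    n_classes: int = 4
    image_size: int = 28
    conv1_filters: int = 6
    conv2_filters: int = 16
    kernel: int = 5
    dense1: int = 128
    dense2: int = 64
    dropout: float = 0.5
    epochs: int = 64
    batch_size: int = 64
    learning_rate: float = 0.005
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if self.n_classes < 2:
            raise ArchitectureError("need at least 2 classes")
        for name in ("image_size", "conv1_filters", "conv2_filters", "kernel",
                     "dense1", "dense2", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ArchitectureError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ArchitectureError("learning_rate must be positive")
        if self.flat_features <= 0:
            raise ArchitectureError(
                f"image size {self.image_size} too small for two conv+pool stages")

    @property
    def flat_features(self) -> int:
        s = self.image_size
        for _ in range(2):                   # two conv + pool stages
            s = s - self.kernel + 1
            if s < 1:
                return 0
            s = s // 2
            if s < 1:
                return 0
        return self.conv2_filters * s * s


@dataclass(frozen=True)
class TrainedNet:
    net_id: str
    spec: NetSpec
    params: dict
    seed: int
    train_label: str = ""


@dataclass(frozen=True)
class NetPrediction:
    instance_id: str
    probabilities: np.ndarray
    entropy: float


# ---------------------------------------------------------------------------
# Layer primitives (im2col convolution, 2x2 max pool, dense, dropout)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int):
    """(N, C, H, W) -> (N, OH*OW, C*k*k) patch matrix."""
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N,C,OH,OW,k,k)
    n, c, oh, ow = win.shape[:4]
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * k * k)
    return np.ascontiguousarray(col), oh, ow


def _conv_forward(x, w, b, k):
    col, oh, ow = _im2col(x, k)
    out = col @ w + b                                  # (N, OH*OW, F)
    out = out.transpose(0, 2, 1).reshape(x.shape[0], w.shape[1], oh, ow)
    return out, (col, x.shape, oh, ow)


def _conv_backward(dout, w, k, cache):
    col, xshape, oh, ow = cache
    n, c = xshape[0], xshape[1]
    f = w.shape[1]
    dflat = dout.reshape(n, f, oh * ow).transpose(0, 2, 1)   # (N, OH*OW, F)
    dw = np.tensordot(col, dflat, axes=([0, 1], [0, 1]))     # (C*k*k, F)
    db = dflat.sum(axis=(0, 1))
    dcol = dflat @ w.T                                        # (N, OH*OW, C*k*k)
    dcol = dcol.reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    dx = np.zeros(xshape)
    for i in range(k):
        for j in range(k):
            dx[:, :, i:i + oh, j:j + ow] += dcol[:, :, :, :, i, j]
    return dx, dw, db


def _pool_forward(x):
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    patches = (x[:, :, :h2 * 2, :w2 * 2]
               .reshape(n, c, h2, 2, w2, 2)
               .transpose(0, 1, 2, 4, 3, 5)
               .reshape(n, c, h2, w2, 4))
    idx = patches.argmax(axis=-1)                 # first max on ties
    out = np.take_along_axis(patches, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def _pool_backward(dout, cache):
    idx, xshape = cache
    n, c, h, w = xshape
    h2, w2 = h // 2, w // 2
    dpatch = np.zeros((n, c, h2, w2, 4))
    np.put_along_axis(dpatch, idx[..., None], dout[..., None], axis=-1)
    dx = (dpatch.reshape(n, c, h2, w2, 2, 2)
          .transpose(0, 1, 2, 4, 3, 5)
          .reshape(n, c, h2 * 2, w2 * 2))
    if (h2 * 2, w2 * 2) != (h, w):
        full = np.zeros(xshape)
        full[:, :, :h2 * 2, :w2 * 2] = dx
        dx = full
    return dx


def _dropout(x, p, rng):
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * mask, mask


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Parameter initialization
# ---------------------------------------------------------------------------

def _init_params(spec: NetSpec, rng: np.random.Generator) -> dict:
    k = spec.kernel

    def he(shape, fan_in):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    p = {}
    p["w1"] = he((1 * k * k, spec.conv1_filters), 1 * k * k)
    p["b1"] = np.zeros(spec.conv1_filters)
    p["w2"] = he((spec.conv1_filters * k * k, spec.conv2_filters),
                 spec.conv1_filters * k * k)
    p["b2"] = np.zeros(spec.conv2_filters)
    p["w3"] = he((spec.flat_features, spec.dense1), spec.flat_features)
    p["b3"] = np.zeros(spec.dense1)
    p["w4"] = he((spec.dense1, spec.dense2), spec.dense1)
    p["b4"] = np.zeros(spec.dense2)
    limit = np.sqrt(6.0 / (spec.dense2 + spec.n_classes))
    p["w5"] = rng.uniform(-limit, limit, size=(spec.dense2, spec.n_classes))
    p["b5"] = np.zeros(spec.n_classes)
    return p


def _forward(params, spec, x, rng=None):
    """Forward pass; dropout is applied iff a generator is supplied."""
    k, p_drop = spec.kernel, spec.dropout
    caches = {}
    a, caches["conv1"] = _conv_forward(x, params["w1"], params["b1"], k)
    caches["relu1"] = a > 0
    a = np.maximum(a, 0)
    a, caches["pool1"] = _pool_forward(a)
    if rng is not None:
        a, caches["drop1"] = _dropout(a, p_drop, rng)
    a, caches["conv2"] = _conv_forward(a, params["w2"], params["b2"], k)
    caches["relu2"] = a > 0
    a = np.maximum(a, 0)
    a, caches["pool2"] = _pool_forward(a)
    if rng is not None:
        a, caches["drop2"] = _dropout(a, p_drop, rng)
    caches["flat_shape"] = a.shape
    a = a.reshape(a.shape[0], -1)
    z3 = a @ params["w3"] + params["b3"]
    caches["in3"], caches["relu3"] = a, z3 > 0
    a = np.maximum(z3, 0)
    if rng is not None:
        a, caches["drop3"] = _dropout(a, p_drop, rng)
    z4 = a @ params["w4"] + params["b4"]
    caches["in4"], caches["relu4"] = a, z4 > 0
    a = np.maximum(z4, 0)
    if rng is not None:
        a, caches["drop4"] = _dropout(a, p_drop, rng)
    caches["in5"] = a
    logits = a @ params["w5"] + params["b5"]
    return logits, caches


def _backward(params, spec, caches, dlogits):
    g = {}
    a = caches["in5"]
    g["w5"] = a.T @ dlogits
    g["b5"] = dlogits.sum(axis=0)
    da = dlogits @ params["w5"].T
    if "drop4" in caches:
        da = da * caches["drop4"]
    da = da * caches["relu4"]
    g["w4"] = caches["in4"].T @ da
    g["b4"] = da.sum(axis=0)
    da = da @ params["w4"].T
    if "drop3" in caches:
        da = da * caches["drop3"]
    da = da * caches["relu3"]
    g["w3"] = caches["in3"].T @ da
    g["b3"] = da.sum(axis=0)
    da = da @ params["w3"].T
    da = da.reshape(caches["flat_shape"])
    if "drop2" in caches:
        da = da * caches["drop2"]
    da = _pool_backward(da, caches["pool2"])
    da = da * caches["relu2"]
    da, g["w2"], g["b2"] = _conv_backward(da, params["w2"], spec.kernel,
                                          caches["conv2"])
    if "drop1" in caches:
        da = da * caches["drop1"]
    da = _pool_backward(da, caches["pool1"])
    da = da * caches["relu1"]
    _, g["w1"], g["b1"] = _conv_backward(da, params["w1"], spec.kernel,
                                         caches["conv1"])
    return g


# ---------------------------------------------------------------------------
# Training and evaluation
# ---------------------------------------------------------------------------

def _as_batch_input(x: np.ndarray, spec: NetSpec) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 3:
        x = x[:, None, :, :]
    if x.shape[2] != spec.image_size or x.shape[3] != spec.image_size:
        raise ArchitectureError(
            f"images are {x.shape[2]}x{x.shape[3]}, spec expects "
            f"{spec.image_size}x{spec.image_size}")
    return x


def train_network(spec: NetSpec, train_images, train_labels, seed: int,
                  net_id: str = "net0", train_label: str = "",
                  epochs: int | None = None) -> TrainedNet:
    """Train one randomly initialized network exactly per the protocol.

    `epochs` overrides the spec's epoch count for explicitly
    scaled-down runs; the override is logged.
    """
    x = _as_batch_input(train_images, spec)
    y = np.asarray(train_labels, dtype=int)
    if len(x) == 0:
        raise ArchitectureError("training set is empty")
    if y.min() < 0 or y.max() >= spec.n_classes:
        raise ArchitectureError("labels outside [0, n_classes)")
    n_epochs = spec.epochs if epochs is None else epochs
    if epochs is not None and epochs != spec.epochs:
        logger.info("%s: training %d epochs (protocol value %d)",
                    net_id, epochs, spec.epochs)
    rng = np.random.default_rng(seed)
    params = _init_params(spec, rng)
    onehot = np.eye(spec.n_classes)[y]
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(val) for k, val in params.items()}
    t = 0
    b1, b2, eps, lr = (spec.adam_beta1, spec.adam_beta2,
                       spec.adam_eps, spec.learning_rate)
    n = len(x)
    for _ in range(n_epochs):
        order = rng.permutation(n)
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            xb, yb = x[idx], onehot[idx]
            logits, caches = _forward(params, spec, xb, rng=rng)
            probs = _softmax(logits)
            dlogits = (probs - yb) / len(idx)
            grads = _backward(params, spec, caches, dlogits)
            t += 1
            for key in params:
                m[key] = b1 * m[key] + (1 - b1) * grads[key]
                v[key] = b2 * v[key] + (1 - b2) * grads[key] ** 2
                mhat = m[key] / (1 - b1 ** t)
                vhat = v[key] / (1 - b2 ** t)
                params[key] = params[key] - lr * mhat / (np.sqrt(vhat) + eps)
    return TrainedNet(net_id=net_id, spec=spec, params=params, seed=seed,
                      train_label=train_label)


def predict_proba(net: TrainedNet, images) -> np.ndarray:
    """Softmax class probabilities with dropout disabled, batched for memory."""
    x = _as_batch_input(images, net.spec)
    chunks = []
    for start in range(0, len(x), 256):
        logits, _ = _forward(net.params, net.spec, x[start:start + 256], rng=None)
        chunks.append(_softmax(logits))
    return np.concatenate(chunks)


def evaluate_accuracy(net: TrainedNet, images, labels) -> float:
    """Fraction of argmax-correct predictions (probability ties -> lowest class)."""
    y = np.asarray(labels, dtype=int)
    if len(y) == 0:
        raise ArchitectureError("test set is empty")
    probs = predict_proba(net, images)
    return float((probs.argmax(axis=1) == y).mean())


def prediction_entropy(probs: np.ndarray) -> np.ndarray:
    """Row-wise entropy in nats with 0*ln(0) = 0."""
    p = np.asarray(probs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=-1)


def confidence(net: TrainedNet, images, instance_ids) -> list:
    """Per-instance output distributions and entropies (inference mode)."""
    probs = predict_proba(net, images)
    ent = prediction_entropy(probs)
    return [NetPrediction(instance_id=iid, probabilities=probs[i],
                          entropy=float(ent[i]))
            for i, iid in enumerate(instance_ids)]


@dataclass
class EnsembleResult:
    nets: list
    accuracies: list                 # aligned with nets
    confidences: pd.DataFrame        # rows: instance_id, columns: net_id, entropies

    @property
    def mean_entropy(self) -> pd.Series:
        return self.confidences.mean(axis=1)


def train_ensemble(spec: NetSpec, train_images, train_labels, n_nets: int,
                   base_seed: int, eval_images, eval_ids,
                   test_images=None, test_labels=None,
                   train_label: str = "", epochs: int | None = None) -> EnsembleResult:
    """Train `n_nets` networks seeded base_seed + i; collect accuracy and confidence.

    Confidence entropies are evaluated on `eval_images`; test accuracy
    (if a test set is given) on `test_images`.
    """
    if n_nets < 1:
        raise ArchitectureError("n_nets must be >= 1")
    nets, accs, ent_cols = [], [], {}
    for i in range(n_nets):
        net_id = f"{train_label or 'net'}_{i:03d}"
        try:
            net = train_network(spec, train_images, train_labels,
                                seed=base_seed + i, net_id=net_id,
                                train_label=train_label, epochs=epochs)
        except Exception as exc:
            raise RuntimeError(f"ensemble member {i} failed: {exc}") from exc
        nets.append(net)
        if test_images is not None:
            accs.append(evaluate_accuracy(net, test_images, test_labels))
        probs = predict_proba(net, eval_images)
        ent_cols[net_id] = prediction_entropy(probs)
    conf = pd.DataFrame(ent_cols, index=pd.Index(eval_ids, name="instance_id"))
    return EnsembleResult(nets=nets, accuracies=accs, confidences=conf)
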