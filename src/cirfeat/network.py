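"""Compact convolutional classifier for residue-pair feature matrices.

The network mirrors the architecture used for core-interacting-residue
classification: two convolutional layers followed by a dropout layer, a
flatten step and two dense layers ending in a single sigmoid unit that
scores the probability that the input pair sits at the core of an
interface.  Inputs are the normalised complementarity matrices (rows =
feature kinds, columns = partner + 9 neighbors).

The implementation is pure numpy (im2col convolutions, Adam, binary
cross-entropy, early stopping on validation loss): the input is 3×10, so
desk-scale training takes seconds and the whole stack stays dependency-light
and bit-reproducible under a fixed seed on one platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve, auc as _sk_auc

__all__ = [
    "ClassifierConfig",
    "CIRNet",
    "PredictionSet",
    "train",
    "predict",
    "roc_curve_auc",
    "apply_threshold",
    "UNIVERSAL_THRESHOLD",
]

#: Universal decision cut-off on the network score.
UNIVERSAL_THRESHOLD = 0.38


class ConfigError(ValueError):
    """Raised for invalid classifier configurations."""


@dataclass
class ClassifierConfig:
    """Hyperparameters of the two-conv/two-dense classifier.

    Defaults are sized for a 3×10 input: 16 and 32 3×3 filters with 'same'
    zero padding, dropout 0.25 after the convolutions, a 64-unit hidden
    dense layer, Adam at 1e-3, at most 200 epochs with patience 20 on the
    validation loss, batch size 64.
    """

    conv_filters: tuple = (16, 32)
    kernel_size: tuple = (3, 3)
    dropout: float = 0.25
    dense_units: int = 64
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 64
    patience: int = 20
    seed: int = 1337

    def validate(self, input_shape: tuple) -> None:
        kh, kw = self.kernel_size
        h, w = input_shape
        if kh % 2 == 0 or kw % 2 == 0:
            raise ConfigError("kernel dimensions must be odd for 'same' padding")
        if kw > w or kh > max(h, kh // 2 * 2 + 1) + 2 * (kh // 2):
            raise ConfigError(f"kernel {self.kernel_size} larger than input {input_shape}")
        if not 0 <= self.dropout < 1:
            raise ConfigError("dropout must be in [0, 1)")
        if len(self.conv_filters) != 2:
            raise ConfigError("exactly two convolutional layers are required")


def _conv_forward(x, w, b):
    n, c, h, wd = x.shape
    f, _, kh, kw = w.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = np.empty((n, c, kh, kw, h, wd))
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + h, j : j + wd]
    out = np.einsum("ncijhw,fcij->nfhw", cols, w, optimize=True) + b[None, :, None, None]
    return out, (cols, x.shape, w)


def _conv_backward(dout, cache):
    cols, xshape, w = cache
    n, c, h, wd = xshape
    _, _, kh, kw = w.shape
    ph, pw = kh // 2, kw // 2
    dw = np.einsum("nfhw,ncijhw->fcij", dout, cols, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    dcols = np.einsum("nfhw,fcij->ncijhw", dout, w, optimize=True)
    dxp = np.zeros((n, c, h + 2 * ph, wd + 2 * pw))
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + h, j : j + wd] += dcols[:, :, i, j]
    return dxp[:, :, ph : ph + h, pw : pw + wd], dw, db


class CIRNet:
    """conv → conv → dropout → flatten → dense → dense → sigmoid."""

    def __init__(self, config: ClassifierConfig, input_shape: tuple = (3, 10)):
        config.validate(input_shape)
        self.config = config
        self.input_shape = tuple(input_shape)
        rng = np.random.default_rng(config.seed)
        f1, f2 = config.conv_filters
        kh, kw = config.kernel_size
        h, w = input_shape
        flat = f2 * h * w

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params = {
            "w1": he((f1, 1, kh, kw), kh * kw),
            "b1": np.zeros(f1),
            "w2": he((f2, f1, kh, kw), f1 * kh * kw),
            "b2": np.zeros(f2),
            "w3": he((flat, config.dense_units), flat),
            "b3": np.zeros(config.dense_units),
            "w4": he((config.dense_units, 1), config.dense_units),
            "b4": np.zeros(1),
        }

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def forward(self, x, train: bool = False, rng: np.random.Generator | None = None):
        """Scores in [0, 1] for a batch; caches intermediates when training."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[:, None]
        p = self.params
        z1, c1 = _conv_forward(x, p["w1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        z2, c2 = _conv_forward(a1, p["w2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        if train and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            mask = (rng.random(a2.shape) < keep) / keep
            d = a2 * mask
        else:
            mask = None
            d = a2
        flat = d.reshape(len(x), -1)
        z3 = flat @ p["w3"] + p["b3"]
        a3 = np.maximum(z3, 0.0)
        z4 = a3 @ p["w4"] + p["b4"]
        score = 1.0 / (1.0 + np.exp(-z4[:, 0]))
        cache = (c1, z1, c2, z2, mask, d.shape, flat, z3, a3, score) if train else None
        return score, cache

    def backward(self, y, cache):
        """Gradients of mean binary cross-entropy w.r.t. all parameters."""
        c1, z1, c2, z2, mask, dshape, flat, z3, a3, score = cache
        p = self.params
        n = len(y)
        dz4 = ((score - y) / n)[:, None]
        grads = {
            "w4": a3.T @ dz4,
            "b4": dz4.sum(axis=0),
        }
        da3 = dz4 @ p["w4"].T
        dz3 = da3 * (z3 > 0)
        grads["w3"] = flat.T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["w3"].T
        dd = dflat.reshape(dshape)
        if mask is not None:
            dd = dd * mask
        dz2 = dd * (z2 > 0)
        da1, grads["w2"], grads["b2"] = _conv_backward(dz2, c2)
        dz1 = da1 * (z1 > 0)
        _, grads["w1"], grads["b1"] = _conv_backward(dz1, c1)
        return grads

    def get_weights(self):
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights):
        self.params = {k: np.asarray(v, dtype=float).copy() for k, v in weights.items()}

    def save(self, path) -> None:
        """Portable archive of weights + config (numpy .npz)."""
        np.savez(
            path,
            **self.params,
            __input_shape=np.asarray(self.input_shape),
            **{f"__cfg_{k}": np.asarray(v) for k, v in asdict(self.config).items()},
        )

    @classmethod
    def load(cls, path) -> "CIRNet":
        with np.load(path) as data:
            cfg = ClassifierConfig(
                conv_filters=tuple(int(v) for v in data["__cfg_conv_filters"]),
                kernel_size=tuple(int(v) for v in data["__cfg_kernel_size"]),
                dropout=float(data["__cfg_dropout"]),
                dense_units=int(data["__cfg_dense_units"]),
                learning_rate=float(data["__cfg_learning_rate"]),
                epochs=int(data["__cfg_epochs"]),
                batch_size=int(data["__cfg_batch_size"]),
                patience=int(data["__cfg_patience"]),
                seed=int(data["__cfg_seed"]),
            )
            model = cls(cfg, tuple(int(v) for v in data["__input_shape"]))
            model.params = {k: data[k] for k in model.params}
        return model


def _bce(score, y):
    eps = 1e-12
    return float(-np.mean(y * np.log(score + eps) + (1 - y) * np.log(1 - score + eps)))


def train(
    model: CIRNet,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    verbose: bool = False,
) -> dict:
    """Adam training with early stopping on validation loss.

    Restores the best-validation weights on exit and returns the history
    (train/val loss and accuracy per epoch).  Aborts on non-finite loss.
    Reproducible under the config seed with single-threaded execution.
    """
    cfg = model.config
    rng = np.random.default_rng(cfg.seed + 1)
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(p) for k, p in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    best_loss = np.inf
    best_weights = model.get_weights()
    wait = 0
    history = {"loss": [], "val_loss": [], "acc": [], "val_acc": []}
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_train))
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            score, cache = model.forward(x_train[idx], train=True, rng=rng)
            grads = model.backward(y_train[idx], cache)
            t += 1
            for k in model.params:
                g = grads[k]
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1**t)
                vhat = v[k] / (1 - beta2**t)
                model.params[k] = model.params[k] - cfg.learning_rate * mhat / (
                    np.sqrt(vhat) + eps
                )
        s_tr, _ = model.forward(x_train)
        s_va, _ = model.forward(x_val)
        loss, val_loss = _bce(s_tr, y_train), _bce(s_va, np.asarray(y_val, dtype=float))
        if not (np.isfinite(loss) and np.isfinite(val_loss)):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}: train={loss}, val={val_loss}"
            )
        history["loss"].append(loss)
        history["val_loss"].append(val_loss)
        history["acc"].append(float(np.mean((s_tr > 0.5) == (y_train > 0.5))))
        history["val_acc"].append(float(np.mean((s_va > 0.5) == (np.asarray(y_val) > 0.5))))
        if verbose:
            print(f"epoch {epoch}: loss={loss:.4f} val_loss={val_loss:.4f}")
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_weights = model.get_weights()
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break
    model.set_weights(best_weights)
    return history


@dataclass
class PredictionSet:
    """Per-pair network score, true label and chemical pair class."""

    scores: np.ndarray
    labels: np.ndarray
    classes: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("scores must lie in [0, 1]")
        if len(self.classes) == 0:
            self.classes = np.array(["--"] * len(self.scores), dtype=object)

    def __len__(self) -> int:
        return len(self.scores)


def predict(
    model: CIRNet,
    x: np.ndarray,
    labels: np.ndarray | None = None,
    classes: np.ndarray | None = None,
    normalized: bool = True,
) -> PredictionSet:
    """Deterministic inference (dropout off) over a batch of feature matrices.

    Refuses obviously unnormalised input (values outside [0, 1]); pass the
    matrices through the training-split :class:`FeatureNormalizer` first.
    """
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        return PredictionSet(np.empty(0), np.empty(0, dtype=int))
    if not normalized or x.min() < -1e-9 or x.max() > 1 + 1e-9:
        raise ValueError("input features must be normalised to [0, 1] before inference")
    scores, _ = model.forward(x)
    labels = np.zeros(len(x), dtype=int) if labels is None else labels
    return PredictionSet(
        scores=scores,
        labels=labels,
        classes=np.asarray(classes, dtype=object) if classes is not None else np.array([], dtype=object),
    )


def roc_curve_auc(predictions: PredictionSet):
    """ROC points and trapezoidal AUC for a prediction set.

    Requires both classes to be present.
    """
    y = predictions.labels
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes to be present")
    fpr, tpr, thr = _sk_roc_curve(y, predictions.scores)
    return fpr, tpr, thr, float(_sk_auc(fpr, tpr))


def apply_threshold(
    predictions: PredictionSet,
    threshold: float | dict = UNIVERSAL_THRESHOLD,
) -> dict:
    """Confusion matrix as fractions of all pairs (cells sum to 1).

    ``threshold`` is either a universal scalar cut-off or a per-pair-class
    map; classes missing from the map fall back to the universal cut-off
    with a warning.
    """
    import warnings

    scores, labels = predictions.scores, predictions.labels
    if isinstance(threshold, dict):
        thr = np.empty(len(scores))
        for i, cls in enumerate(predictions.classes):
            if cls in threshold:
                thr[i] = threshold[cls]
            else:
                warnings.warn(f"no threshold for class {cls}; using universal")
                thr[i] = UNIVERSAL_THRESHOLD
    else:
        if not 0 <= threshold <= 1:
            raise ValueError("threshold must be in [0, 1]")
        thr = np.full(len(scores), float(threshold))
    pred = scores > thr
    n = len(scores)
    return {
        "tp": float(np.sum(pred & (labels == 1))) / n,
        "fp": float(np.sum(pred & (labels == 0))) / n,
        "tn": float(np.sum(~pred & (labels == 0))) / n,
        "fn": float(np.sum(~pred & (labels == 1))) / n,
    }
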