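"""Small CNN for 5-grade diabetic-retinopathy classification.

Architecture: 32x32 input, four blocks of (3x3 stride-1 convolution ->
activation -> 2x2 max pool), then flatten and two fully connected layers
(activation between them, softmax on top).  Trained with categorical
cross-entropy and Nadam.  The activation is resolved by name from the
registry, so the trigonometric ``x/cos x`` activation and the reference
activations are interchangeable without changing shapes or parameter
counts.

The public surface is :class:`FundusCNNClassifier` — an sklearn-style
estimator (``fit`` / ``predict`` / ``predict_proba``, ``get_params`` /
``set_params``) — with thin functional wrappers :func:`build_cnn`,
:func:`train` and :func:`predict` on top of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .activations import get_activation

__all__ = [
    "CNNConfig",
    "TrainConfig",
    "FundusCNNClassifier",
    "build_cnn",
    "train",
    "predict",
    "parameter_count",
    "DivergenceError",
]


class DivergenceError(RuntimeError):
    """Raised when training produces a NaN/Inf loss."""


@dataclass(frozen=True)
class CNNConfig:
    """Architecture description.

    Default: greyscale 32x32 input, conv channels (4, 8, 16, 32),
    3x3 kernels at stride 1, 2x2/2 max pooling, FC widths (64, 5).
    """

    input_size: int = 32
    channels: int = 1
    conv_channels: tuple[int, ...] = (4, 8, 16, 32)
    kernel: int = 3
    pool: int = 2
    fc_hidden: int = 64
    n_classes: int = 5
    activation: str = "proposed"

    def __post_init__(self):
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")
        get_activation(self.activation)  # fail fast on unknown names
        size = self.input_size
        for stage, _ in enumerate(self.conv_channels, start=1):
            if size < self.pool or size % self.pool:
                raise ValueError(
                    f"pool stage {stage} would collapse the feature map: "
                    f"spatial size {size} cannot be pooled by {self.pool}"
                )
            size //= self.pool
        if size < 1:
            raise ValueError("spatial size collapsed below 1x1")

    @property
    def final_spatial(self) -> int:
        return self.input_size // self.pool ** len(self.conv_channels)

    @property
    def flat_features(self) -> int:
        return self.final_spatial**2 * self.conv_channels[-1]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings: Nadam with conventional moment constants."""

    epochs: int = 30
    learning_rate: float = 1e-2
    batch_size: int = 32
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0
    max_grad_norm: float = 1.0
    lr_schedule: str = "cosine"
    warmup_epochs: int = 3

    def __post_init__(self):
        if self.epochs <= 0 or self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("epochs, learning_rate, batch_size must be > 0")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError("lr_schedule must be 'cosine' or 'constant'")


def parameter_count(cfg: CNNConfig) -> int:
    """Closed-form parameter count: sum of (k^2 c_in + 1) c_out over convs
    plus (n_in + 1) n_out over the two fully connected layers."""
    total = 0
    c_in = cfg.channels
    for c_out in cfg.conv_channels:
        total += (cfg.kernel**2 * c_in + 1) * c_out
        c_in = c_out
    total += (cfg.flat_features + 1) * cfg.fc_hidden
    total += (cfg.fc_hidden + 1) * cfg.n_classes
    return total


def _build_network(cfg: CNNConfig) -> nn.Sequential:
    spec = get_activation(cfg.activation)
    layers: list = []
    c_in = cfg.channels
    for c_out in cfg.conv_channels:
        layers += [nn.Conv2D(c_in, c_out, cfg.kernel), nn.ActLayer(spec),
                   nn.MaxPool2D(cfg.pool)]
        c_in = c_out
    layers += [nn.Flatten(),
               nn.Dense(cfg.flat_features, cfg.fc_hidden),
               nn.ActLayer(spec),
               nn.Dense(cfg.fc_hidden, cfg.n_classes)]
    return nn.Sequential(layers)


def _prepare_images(X, input_size: int, channels: int) -> np.ndarray:
    """Stack images into NHWC float64 in [-0.5, 0.5], resizing as needed.

    Accepts a list/array of HxW or HxWx3 uint8/float images.  Colour
    images feeding a 1-channel network are reduced to the green plane.
    Downsampling uses local-mean (area) interpolation.
    """
    from skimage.transform import resize

    out = []
    for img in X:
        arr = np.asarray(img, dtype=float)
        if arr.ndim == 3 and channels == 1:
            arr = arr[..., 1]
        if arr.ndim == 2 and channels == 3:
            arr = np.stack([arr] * 3, axis=-1)
        if arr.ndim == 2:
            arr = arr[..., None]
        if arr.shape[0] != input_size or arr.shape[1] != input_size:
            arr = resize(arr, (input_size, input_size),
                         anti_aliasing=True, preserve_range=True)
        out.append(arr)
    x = np.stack(out)
    # map 0..255 onto [-0.5, 0.5]; keeps pre-activations inside the
    # near-linear region of the clamped trigonometric activation at init
    return x / 255.0 - 0.5


class FundusCNNClassifier(BaseEstimator, ClassifierMixin):
    """4-conv CNN classifier over small fundus images.

    Parameters mirror :class:`CNNConfig` and :class:`TrainConfig`; the
    defaults are the desk-scale study configuration (30 epochs, Nadam at
    learning rate 1e-2, batch size 32).

    Attributes (after ``fit``)
    --------------------------
    classes_ : ndarray of the sorted class labels seen in ``y``.
    history_ : DataFrame with per-epoch ``loss`` and ``accuracy``.
    n_params_ : total trainable parameter count.
    network_ : the underlying :class:`~fundusdr.nn.Sequential`.
    """

    def __init__(self, conv_channels=(4, 8, 16, 32), fc_hidden=64,
                 n_classes=5, activation="proposed", input_size=32,
                 channels=1, epochs=30, learning_rate=1e-2, batch_size=32,
                 max_grad_norm=1.0, lr_schedule="cosine", warmup_epochs=3,
                 random_state=0):
        self.conv_channels = conv_channels
        self.fc_hidden = fc_hidden
        self.n_classes = n_classes
        self.activation = activation
        self.input_size = input_size
        self.channels = channels
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_grad_norm = max_grad_norm
        self.lr_schedule = lr_schedule
        self.warmup_epochs = warmup_epochs
        self.random_state = random_state

    def _cnn_config(self) -> CNNConfig:
        return CNNConfig(
            input_size=self.input_size, channels=self.channels,
            conv_channels=tuple(self.conv_channels), fc_hidden=self.fc_hidden,
            n_classes=self.n_classes, activation=self.activation,
        )

    def fit(self, X, y):
        y = np.asarray(y)
        if y.ndim != 1:
            raise ValueError("y must be 1-D integer grades")
        if np.any((y < 0) | (y >= self.n_classes)):
            raise ValueError(
                f"labels must lie in 0..{self.n_classes - 1}; "
                f"observed range [{y.min()}, {y.max()}]"
            )
        cfg = self._cnn_config()
        x = _prepare_images(X, cfg.input_size, cfg.channels)
        if len(x) != len(y):
            raise ValueError(f"{len(x)} images but {len(y)} labels")
        batch_size = min(self.batch_size, len(x))

        rng = np.random.default_rng(self.random_state)
        net = _build_network(cfg)
        net.init(rng)
        opt = nn.Nadam(net.params(), lr=self.learning_rate)

        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError("lr_schedule must be 'cosine' or 'constant'")

        records = []
        n = len(x)
        for epoch in range(self.epochs):
            warm = (min(1.0, (epoch + 1) / self.warmup_epochs)
                    if self.warmup_epochs else 1.0)
            if self.lr_schedule == "cosine":
                # linear warmup, then anneal toward 0 over the run
                opt.lr = self.learning_rate * warm * 0.5 * (
                    1.0 + np.cos(np.pi * epoch / self.epochs)
                )
            else:
                opt.lr = self.learning_rate * warm
            order = rng.permutation(n)
            epoch_loss, epoch_hits = 0.0, 0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                xb, yb = x[idx], y[idx]
                logits = net.forward(xb)
                loss, dlogits = nn.softmax_xent(logits, yb)
                if not np.isfinite(loss):
                    raise DivergenceError(
                        f"non-finite loss at epoch {epoch + 1} "
                        f"(learning rate {self.learning_rate})"
                    )
                net.backward(dlogits)
                grads = net.grads()
                nn.clip_grad_norm(grads, self.max_grad_norm)
                opt.step(grads)
                epoch_loss += loss * len(idx)
                epoch_hits += int((logits.argmax(axis=1) == yb).sum())
            records.append({
                "epoch": epoch + 1,
                "loss": epoch_loss / n,
                "accuracy": epoch_hits / n,
            })
        self.classes_ = np.arange(self.n_classes)
        self.network_ = net
        self.n_params_ = net.n_params
        self.history_ = pd.DataFrame.from_records(records)
        return self

    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise RuntimeError("classifier is not fitted; call fit first")

    def predict_proba(self, X) -> np.ndarray:
        """Per-image class probabilities (rows sum to 1)."""
        self._check_fitted()
        x = _prepare_images(X, self.input_size, self.channels)
        return nn.softmax(self.network_.forward(x))

    def predict(self, X) -> np.ndarray:
        """Argmax grade per image; ties break to the lowest class index."""
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X, y) -> float:
        return float((self.predict(X) == np.asarray(y)).mean())

    def save(self, path) -> None:
        """Checkpoint the fitted weights and hyperparameters (.npz)."""
        self._check_fitted()
        import json

        arrays = {f"param_{i}": p for i, p in
                  enumerate(self.network_.params())}
        np.savez(path, hyper=json.dumps(self.get_params(), default=list),
                 **arrays)

    @classmethod
    def load(cls, path) -> "FundusCNNClassifier":
        """Rebuild a fitted classifier from a checkpoint."""
        import json

        with np.load(path, allow_pickle=False) as data:
            hyper = json.loads(str(data["hyper"]))
            weights = [data[f"param_{i}"]
                       for i in range(len(data.files) - 1)]
        hyper["conv_channels"] = tuple(hyper["conv_channels"])
        clf = cls(**hyper)
        net = _build_network(clf._cnn_config())
        params = net.params()
        if len(params) != len(weights):
            raise ValueError("checkpoint does not match the architecture")
        for p, w in zip(params, weights):
            p[...] = w
        clf.network_ = net
        clf.classes_ = np.arange(clf.n_classes)
        clf.n_params_ = net.n_params
        return clf


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def build_cnn(cfg: CNNConfig) -> FundusCNNClassifier:
    """Create an (unfitted) classifier from an architecture config."""
    return FundusCNNClassifier(
        conv_channels=cfg.conv_channels, fc_hidden=cfg.fc_hidden,
        n_classes=cfg.n_classes, activation=cfg.activation,
        input_size=cfg.input_size, channels=cfg.channels,
    )


def train(model: FundusCNNClassifier, X, y,
          tcfg: TrainConfig | None = None) -> pd.DataFrame:
    """Fit ``model`` under a :class:`TrainConfig`; returns the history."""
    tcfg = tcfg or TrainConfig()
    model.set_params(
        epochs=tcfg.epochs, learning_rate=tcfg.learning_rate,
        batch_size=tcfg.batch_size, max_grad_norm=tcfg.max_grad_norm,
        lr_schedule=tcfg.lr_schedule, warmup_epochs=tcfg.warmup_epochs,
        random_state=tcfg.seed,
    )
    model.fit(X, y)
    return model.history_


def predict(model: FundusCNNClassifier, X):
    """Probabilities and argmax grades for a fitted model."""
    proba = model.predict_proba(X)
    return proba, proba.argmax(axis=1)
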