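"""Complex-valued CNN classifier for CV-PAC comodulograms.

Architecture: three complex-valued convolutional layers (complex weights,
complex multiplication with the feature maps, split ReLU, complex batch
normalisation) followed by four complex-valued fully connected layers; the
final complex activations are reduced to real class logits (modulus by
default) and trained with softmax cross-entropy under plain SGD.

Training recipe defaults: 800 epochs, batch size 128, learning rate .0025
halved at every multiple of 250 epochs, dropout .2 on the first fully
connected layer, and L2 regularisation (lambda = .004) on the convolution
weights only.  Layer widths/kernel sizes are configurable implementation
choices (3x3 kernels, 16/32/64 channels, FC widths 128/64/32/2 for 10x10
inputs).

The same machinery with real dtype serves as the real-valued CNN baseline
consuming two-layer (real/imaginary) or strength-only images.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from ..core import CVPACImage
from .layers import (
    BatchNorm,
    Conv2d,
    Dropout,
    Flatten,
    Linear,
    Readout,
    SplitReLU,
    cross_entropy,
    softmax,
)

__all__ = [
    "CVCNNConfig",
    "Network",
    "TrainedModel",
    "train",
    "predict",
    "effective_lr",
    "to_complex_array",
    "to_two_layer_real",
    "save_model",
    "load_model",
]

CLASS_MAP = {0: "normal", 1: "pathological"}
LABEL_TO_INT = {v: k for k, v in CLASS_MAP.items()}


@dataclass(frozen=True)
class CVCNNConfig:
    """Architecture + training hyperparameters."""

    conv_channels: tuple[int, ...] = (16, 32, 64)
    kernel_size: int = 3
    fc_widths: tuple[int, ...] = (128, 64, 32)
    n_classes: int = 2
    in_channels: int = 1
    input_shape: tuple[int, int] = (10, 10)
    epochs: int = 800
    batch_size: int = 128
    lr: float = 0.0025
    lr_decay: float = 0.5
    decay_every: int = 250
    dropout_fc1: float = 0.2
    l2_lambda: float = 0.004
    readout: str = "modulus"
    batchnorm: str = "per_part"
    complex_weights: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 3:
            raise ValueError("three convolutional layers expected")
        if len(self.fc_widths) != 3:
            raise ValueError(
                "three hidden FC widths expected (the fourth FC layer is the "
                "class layer)"
            )
        for name in ("epochs", "batch_size", "lr", "decay_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def small(cls, **overrides) -> "CVCNNConfig":
        """A lighter configuration for desk-scale experiments."""
        defaults = dict(
            conv_channels=(4, 8, 8),
            fc_widths=(32, 16, 8),
            epochs=200,
            batch_size=128,
            lr=0.0025,
        )
        defaults.update(overrides)
        return cls(**defaults)


def effective_lr(config: CVCNNConfig, epoch: int) -> float:
    """Learning rate in force during a given (1-based) epoch.

    The rate halves when the epoch counter passes each multiple of
    ``decay_every``: epochs 1..249 run at lr, 250..499 at lr/2, etc.
    """
    return config.lr * config.lr_decay ** (epoch // config.decay_every)


class Network:
    """Sequential stack of layers built from a config."""

    def __init__(self, config: CVCNNConfig) -> None:
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        cw = config.complex_weights
        layers: list = []
        in_c = config.in_channels
        for out_c in config.conv_channels:
            layers.append(Conv2d(in_c, out_c, config.kernel_size, self.rng, cw))
            layers.append(BatchNorm(out_c, cw, mode=config.batchnorm))
            layers.append(SplitReLU())
            in_c = out_c
        layers.append(Flatten())
        width = in_c * config.input_shape[0] * config.input_shape[1]
        for i, fc_w in enumerate(config.fc_widths):
            layers.append(Linear(width, fc_w, self.rng, cw))
            if i == 0 and config.dropout_fc1 > 0:
                layers.append(Dropout(config.dropout_fc1, self.rng))
            layers.append(SplitReLU())
            width = fc_w
        layers.append(Linear(width, config.n_classes, self.rng, cw))
        layers.append(Readout(config.readout if cw else "real"))
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def parameters(self):
        for layer in self.layers:
            for name, value in layer.params.items():
                yield layer, name, value

    def sgd_step(self, lr: float, l2_lambda: float) -> None:
        for layer, name, value in self.parameters():
            grad = layer.grads[name]
            if getattr(layer, "is_conv", False) and name == "W" and l2_lambda > 0:
                grad = grad + l2_lambda * value
            layer.params[name] = value - lr * grad

    def l2_penalty(self, l2_lambda: float) -> float:
        """The regularisation term (lambda/2) * sum |W_conv|^2."""
        total = 0.0
        for layer, name, value in self.parameters():
            if getattr(layer, "is_conv", False) and name == "W":
                total += float(np.sum(np.abs(value) ** 2))
        return 0.5 * l2_lambda * total


@dataclass
class TrainedModel:
    network: Network
    config: CVCNNConfig
    training_log: list[float] = field(default_factory=list)
    class_map: dict[int, str] = field(default_factory=lambda: dict(CLASS_MAP))


def to_complex_array(images: Sequence[CVPACImage] | np.ndarray) -> np.ndarray:
    """Stack comodulograms into a (n, 1, rows, cols) complex array."""
    if isinstance(images, np.ndarray):
        arr = np.asarray(images, complex)
        if arr.ndim == 3:
            arr = arr[:, None]
        return arr
    return np.stack([im.pixels for im in images])[:, None]


def to_two_layer_real(
    images: Sequence[CVPACImage] | np.ndarray, mode: str = "two_layer"
) -> np.ndarray:
    """Real-valued input for baselines.

    ``"two_layer"``: channel 0 = real part, channel 1 = imaginary part.
    ``"strength"``: a single channel holding the modulus only (the coupling
    strength, discarding the coupled phase).
    """
    z = to_complex_array(images)[:, 0]
    if mode == "two_layer":
        return np.stack([z.real, z.imag], axis=1)
    if mode == "strength":
        return np.abs(z)[:, None]
    raise ValueError(f"unknown representation {mode!r}")


def _encode_labels(labels) -> np.ndarray:
    out = np.empty(len(labels), int)
    for i, lab in enumerate(labels):
        out[i] = LABEL_TO_INT[lab] if isinstance(lab, str) else int(lab)
    return out


def train(
    dataset: Sequence[CVPACImage] | np.ndarray,
    labels=None,
    config: CVCNNConfig | None = None,
) -> TrainedModel:
    """Train a classifier on labelled comodulograms.

    ``dataset`` is either a list of labelled CVPACImage (labels taken from
    the images) or an input array with ``labels`` given separately; real
    arrays train the real-valued baseline when the config says so.
    Deterministic for a fixed config seed.
    """
    config = config or CVCNNConfig()
    if labels is None:
        labels = [im.label for im in dataset]
        if any(lab is None for lab in labels):
            raise ValueError("dataset contains unlabelled images")
    y = _encode_labels(labels)
    if np.unique(y).size < 2:
        raise ValueError("training requires at least two classes")
    if config.complex_weights:
        x = to_complex_array(dataset)
    else:
        x = dataset if isinstance(dataset, np.ndarray) else to_two_layer_real(dataset)
    if x.shape[1] != config.in_channels:
        raise ValueError(
            f"input has {x.shape[1]} channels, config expects {config.in_channels}"
        )
    net = Network(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = x.shape[0]
    log: list[float] = []
    for epoch in range(1, config.epochs + 1):
        lr = effective_lr(config, epoch)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if idx.size < 2:
                continue  # batch norm needs >= 2 samples
            net.zero_grad()
            logits = net.forward(x[idx], train=True)
            loss, grad = cross_entropy(logits, y[idx])
            loss += net.l2_penalty(config.l2_lambda)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            net.backward(grad)
            net.sgd_step(lr, config.l2_lambda)
            losses.append(loss)
        log.append(float(np.mean(losses)))
    return TrainedModel(network=net, config=config, training_log=log)


def predict(
    model: TrainedModel, images: Sequence[CVPACImage] | np.ndarray
) -> np.ndarray:
    """Class probabilities, shape (n, n_classes); column 1 = pathological."""
    if model.config.complex_weights:
        x = to_complex_array(images)
    else:
        x = (
            images
            if isinstance(images, np.ndarray)
            else to_two_layer_real(images)
        )
    logits = model.network.forward(x, train=False)
    return softmax(logits)


def save_model(path, model: TrainedModel) -> None:
    """Self-describing checkpoint: config JSON + per-layer weight arrays."""
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(model.network.layers):
        for name, value in layer.params.items():
            arrays[f"layer{i}.{name}"] = value
        if isinstance(layer, BatchNorm):
            arrays[f"layer{i}.running_mean"] = layer.running_mean
            arrays[f"layer{i}.running_var_re"] = layer.running_var_re
            arrays[f"layer{i}.running_var_im"] = layer.running_var_im
            arrays[f"layer{i}.running_cov"] = layer.running_cov
    cfg = asdict(model.config)
    cfg["conv_channels"] = list(cfg["conv_channels"])
    cfg["fc_widths"] = list(cfg["fc_widths"])
    cfg["input_shape"] = list(cfg["input_shape"])
    np.savez_compressed(
        path,
        config=np.array(json.dumps(cfg)),
        training_log=np.array(model.training_log),
        **arrays,
    )


def load_model(path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as z:
        cfg = json.loads(str(z["config"]))
        for key in ("conv_channels", "fc_widths", "input_shape"):
            cfg[key] = tuple(cfg[key])
        config = CVCNNConfig(**cfg)
        net = Network(config)
        for i, layer in enumerate(net.layers):
            for name in layer.params:
                layer.params[name] = z[f"layer{i}.{name}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean = z[f"layer{i}.running_mean"]
                layer.running_var_re = z[f"layer{i}.running_var_re"]
                layer.running_var_im = z[f"layer{i}.running_var_im"]
                layer.running_cov = z[f"layer{i}.running_cov"]
        log = [float(v) for v in z["training_log"]]
    return TrainedModel(network=net, config=config, training_log=log)
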