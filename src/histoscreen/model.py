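"""The patch-classification CNN and its dense whole-slide application.

The default topology mirrors the classic small patch classifier for
histopathology: four 3x3 convolution blocks (16/32/64/128 filters), each
followed by 2x2 max pooling ("feature extraction"), then three dense layers
(256/128/2, "classification") with a softmax output.  On a 128 px patch the
spatial chain is 128 -> 126 -> 63 -> 61 -> 30 -> 28 -> 14 -> 12 -> 6, so the
first dense layer sees a 6x6x128 block.

Training is stochastic gradient descent with momentum on balanced patch
sets, monitored by the validation-set misclassification rate, stopping when
that rate has not improved for ``patience_epochs`` (default 5) consecutive
epochs and returning the best epoch's weights.

For whole-slide inference the dense layers are rewritten as convolutions
(kernel = remaining spatial extent, then 1x1), turning the patch classifier
into a fully convolutional network.  Because all convolutions are valid and
pool strides are 2, the dense output grid has stride ``2**n_pools`` (16 for
the default) and each grid value equals — bit-for-bit up to BLAS reduction
order — the patch network's output for the patch at that position.  Pixels
between grid positions take the nearest grid value; pixels outside the
tissue mask are zero.  Positions whose receptive field exits the slide see
white background padding, matching the white margins of a scanned slide.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, ConversionError, GeometryError, TrainingError
from .nn import (
    Conv2D,
    Dense,
    Flatten,
    MaxPool2,
    ReLU,
    SGDMomentum,
    softmax,
    softmax_cross_entropy,
)
from .patches import resample_to_mpp
from .preprocess import BinaryMask
from .slide import LikelihoodMap, SlideImage

__all__ = [
    "CNNConfig",
    "PatchCNN",
    "DenseCNN",
    "TrainedModel",
    "EarlyStopping",
    "simulate_early_stopping",
    "build_cnn",
    "train",
    "to_fully_convolutional",
    "infer_likelihood_map",
    "save_model",
    "load_model",
]

#: White padding value used for receptive fields that exit the slide.
PAD_VALUE = 255


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and optimization settings for the patch CNN.

    ``conv_blocks`` is a tuple of ``(n_filters, kernel_size, maxpool)``
    triples; ``fc_sizes`` are the three classification layers, the last of
    which must have 2 units (benign / cancer).
    """

    conv_blocks: tuple = ((16, 3, True), (32, 3, True), (64, 3, True), (128, 3, True))
    fc_sizes: tuple = (256, 128, 2)
    input_px: int = 128
    learning_rate: float = 0.003
    momentum: float = 0.9
    batch_size: int = 64
    max_epochs: int = 20
    patience_epochs: int = 5
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if len(self.fc_sizes) != 3 or self.fc_sizes[-1] != 2:
            raise ConfigurationError("fc_sizes must be three layers ending in 2 units")
        if self.input_px <= 0:
            raise ConfigurationError("input_px must be positive")
        _spatial_chain(self)  # validates the conv/pool chain

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


def _spatial_chain(config: CNNConfig) -> list[int]:
    """Spatial extents after each conv block; raises on underflow."""
    s = config.input_px
    sizes = [s]
    for i, (n_filters, kernel, pool) in enumerate(config.conv_blocks):
        if n_filters <= 0 or kernel <= 0:
            raise ConfigurationError(f"conv block {i}: invalid filters/kernel")
        if s < kernel:
            raise ConfigurationError(
                f"conv block {i}: spatial extent {s} smaller than kernel {kernel}"
            )
        s = s - kernel + 1
        if pool:
            s //= 2
        if s < 1:
            raise ConfigurationError(f"conv block {i}: spatial extent collapsed to {s}")
        sizes.append(s)
    return sizes


class PatchCNN:
    """Patch in, 2-class probability out."""

    def __init__(self, config: CNNConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        dtype = config.np_dtype
        sizes = _spatial_chain(config)
        self.layers = []
        in_ch = 3
        for n_filters, kernel, pool in config.conv_blocks:
            self.layers.append(Conv2D(in_ch, n_filters, kernel, rng=rng, dtype=dtype))
            self.layers.append(ReLU())
            if pool:
                self.layers.append(MaxPool2())
            in_ch = n_filters
        self.final_spatial = sizes[-1]
        self.final_channels = in_ch
        self.layers.append(Flatten())
        n_in = self.final_spatial**2 * in_ch
        for i, n_out in enumerate(config.fc_sizes):
            self.layers.append(Dense(n_in, n_out, rng=rng, dtype=dtype))
            if i < len(config.fc_sizes) - 1:
                self.layers.append(ReLU())
            n_in = n_out

    # -- forward / training ------------------------------------------------

    def _prep(self, patches: np.ndarray) -> np.ndarray:
        """uint8 patches -> per-channel [0, 1] network input."""
        return (np.asarray(patches) / 255.0).astype(self.config.np_dtype)

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        dy = dlogits
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def predict_proba(self, patches: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """(N, p, p, 3) uint8 patches -> (N, 2) softmax probabilities."""
        x = self._prep(patches)
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward_logits(x[i : i + batch_size])))
        return np.concatenate(out, axis=0)

    # -- parameter plumbing ------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p[...] = w


def build_cnn(config: CNNConfig) -> PatchCNN:
    """Instantiate an untrained patch CNN; deterministic given ``config.seed``."""
    return PatchCNN(config)


# ---------------------------------------------------------------------------
# early stopping


class EarlyStopping:
    """Patience-based early stopping on the validation misclassification rate.

    ``update`` is called once per epoch (1-based) and returns True when
    training should stop: the rate has not strictly improved for
    ``patience`` consecutive epochs.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.epochs_since_improvement = 0

    def update(self, epoch: int, val_error: float) -> bool:
        if val_error < self.best:
            self.best = val_error
            self.best_epoch = epoch
            self.epochs_since_improvement = 0
        else:
            self.epochs_since_improvement += 1
        return self.epochs_since_improvement >= self.patience


def simulate_early_stopping(val_errors, patience: int) -> tuple[int, int]:
    """Apply the stopping rule to a given validation-error sequence.

    Returns ``(stopped_epoch, best_epoch)`` (both 1-based); useful for
    verifying the rule without training.
    """
    stopper = EarlyStopping(patience)
    epoch = 0
    for epoch, err in enumerate(val_errors, start=1):
        if stopper.update(epoch, err):
            break
    return epoch, stopper.best_epoch


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainedModel:
    """A trained patch CNN plus its training history."""

    network: PatchCNN
    config: CNNConfig
    history: dict = field(default_factory=dict)  # train_error / val_error lists
    best_epoch: int = 0
    stopped_epoch: int = 0

    def predict_proba(self, patches: np.ndarray, batch_size: int = 128) -> np.ndarray:
        return self.network.predict_proba(patches, batch_size=batch_size)


def _misclassification_rate(network: PatchCNN, X: np.ndarray, y: np.ndarray,
                            batch_size: int) -> float:
    probs = network.predict_proba(X, batch_size=batch_size)
    return float((probs.argmax(axis=1) != y).mean())


def train(
    model: PatchCNN,
    train_patches: tuple[np.ndarray, np.ndarray],
    val_patches: tuple[np.ndarray, np.ndarray],
    config: CNNConfig | None = None,
) -> TrainedModel:
    """SGD training with validation-monitored early stopping.

    ``train_patches`` / ``val_patches`` are ``(X, y)`` with X uint8
    ``(N, p, p, 3)`` and integer labels.  Returns the weights of the epoch
    with the lowest validation misclassification rate.
    """
    config = config or model.config
    Xtr, ytr = train_patches
    Xva, yva = val_patches
    if len(Xtr) == 0 or len(Xva) == 0:
        raise TrainingError("training and validation sets must be non-empty")
    ytr = np.asarray(ytr, dtype=np.int64)
    yva = np.asarray(yva, dtype=np.int64)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed + 1))
    opt = SGDMomentum(model.parameters(), config.learning_rate, config.momentum)
    stopper = EarlyStopping(config.patience_epochs)
    history: dict = {"train_error": [], "val_error": []}
    best_weights = model.get_weights()
    stopped_epoch = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(Xtr))
        batch_errors = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = model._prep(Xtr[idx])
            yb = ytr[idx]
            logits = model.forward_logits(xb, train=True)
            try:
                _, dlogits = softmax_cross_entropy(logits, yb)
            except TrainingError as exc:
                raise TrainingError(f"epoch {epoch}: {exc}") from exc
            batch_errors.append(float((logits.argmax(axis=1) != yb).mean()))
            model.backward(dlogits)
            opt.step(model.gradients())
        history["train_error"].append(float(np.mean(batch_errors)))
        val_err = _misclassification_rate(model, Xva, yva, config.batch_size)
        history["val_error"].append(val_err)
        improved = val_err < stopper.best
        stop = stopper.update(epoch, val_err)
        if improved:
            best_weights = model.get_weights()
        stopped_epoch = epoch
        if stop:
            break

    model.set_weights(best_weights)
    return TrainedModel(
        network=model,
        config=config,
        history=history,
        best_epoch=stopper.best_epoch,
        stopped_epoch=stopped_epoch,
    )


# ---------------------------------------------------------------------------
# checkpoints


def save_model(tm: TrainedModel, prefix) -> None:
    """Write ``<prefix>.npz`` (weights) and ``<prefix>.json`` (config + history)."""
    prefix = Path(prefix)
    weights = tm.network.get_weights()
    np.savez(prefix.with_suffix(".npz"), *weights)
    meta = {
        "config": dataclasses.asdict(tm.config),
        "history": tm.history,
        "best_epoch": tm.best_epoch,
        "stopped_epoch": tm.stopped_epoch,
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_model(prefix) -> TrainedModel:
    """Rebuild a trained model from a checkpoint pair written by save_model."""
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    cfg_dict = meta["config"]
    cfg_dict["conv_blocks"] = tuple(tuple(b) for b in cfg_dict["conv_blocks"])
    cfg_dict["fc_sizes"] = tuple(cfg_dict["fc_sizes"])
    config = CNNConfig(**cfg_dict)
    net = build_cnn(config)
    with np.load(prefix.with_suffix(".npz")) as data:
        net.set_weights([data[f"arr_{i}"] for i in range(len(data.files))])
    return TrainedModel(
        network=net,
        config=config,
        history=meta["history"],
        best_epoch=meta["best_epoch"],
        stopped_epoch=meta["stopped_epoch"],
    )


# ---------------------------------------------------------------------------
# fully convolutional conversion and dense inference


class DenseCNN:
    """The patch CNN with dense layers rewritten as convolutions."""

    def __init__(self, layers, stride: int, input_px: int, dtype):
        self.layers = layers
        self.stride = stride  # output-grid stride in input pixels
        self.input_px = input_px
        self.dtype = dtype

    def forward(self, image01: np.ndarray) -> np.ndarray:
        """(H, W, 3) array in [0, 1] -> (Gh, Gw) class-1 probability grid."""
        x = image01[None].astype(self.dtype)
        for layer in self.layers:
            x = layer.forward(x)
        return softmax(x.astype(np.float64), axis=-1)[0, :, :, 1]


def to_fully_convolutional(model: TrainedModel | PatchCNN) -> DenseCNN:
    """Rewrite the trained patch classifier as a fully convolutional network.

    Dense-layer weights are reshaped into convolution kernels (the first
    over the remaining spatial extent, the rest 1x1); conv/pool layers are
    reused as-is.  The dense output at grid position ``p`` equals the patch
    network's class-1 probability for the patch starting at pixel
    ``stride * p``.
    """
    net = model.network if isinstance(model, TrainedModel) else model
    config = net.config
    dtype = config.np_dtype
    layers = []
    stride = 1
    dense_seen = 0
    s = net.final_spatial
    in_ch = net.final_channels
    for layer in net.layers:
        if isinstance(layer, ReLU):
            layers.append(layer)
        elif isinstance(layer, (Conv2D, MaxPool2)):
            if dense_seen:
                raise ConversionError("conv layer after dense layers is not convertible")
            layers.append(layer)
            if isinstance(layer, MaxPool2):
                stride *= 2
        elif isinstance(layer, Flatten):
            continue
        elif isinstance(layer, Dense):
            kernel = s if dense_seen == 0 else 1
            if layer.n_in != kernel * kernel * in_ch:
                raise ConversionError(
                    f"dense layer of {layer.n_in} inputs does not match the "
                    f"{kernel}x{kernel}x{in_ch} feature block"
                )
            conv = Conv2D(in_ch, layer.n_out, kernel, rng=None, dtype=dtype)
            conv.W[...] = layer.W.reshape(kernel, kernel, in_ch, layer.n_out)
            conv.b[...] = layer.b
            layers.append(conv)
            in_ch = layer.n_out
            dense_seen += 1
        else:  # pragma: no cover - no other layer types exist
            raise ConversionError(f"layer {type(layer).__name__} is not convertible")
    return DenseCNN(layers, stride=stride, input_px=config.input_px, dtype=dtype)


def infer_likelihood_map(
    dense: DenseCNN,
    slide: SlideImage,
    tissue: BinaryMask,
    target_mpp: float,
) -> LikelihoodMap:
    """Dense whole-slide inference at the analysis resolution.

    The slide is resampled to ``target_mpp``, padded with white background
    by half a patch on every side, and pushed through the FCN once.  Grid
    outputs (stride ``dense.stride``) are spread to full resolution by
    nearest-neighbor assignment, then non-tissue pixels are zeroed.
    """
    img = resample_to_mpp(slide.image, slide.microns_per_pixel, target_mpp)
    h, w = img.shape[:2]
    if tissue.shape != (h, w):
        raise GeometryError(
            f"tissue mask {tissue.shape} does not match analysis raster {(h, w)}"
        )
    half = dense.input_px // 2
    padded = np.full((h + 2 * half, w + 2 * half, 3), PAD_VALUE, dtype=img.dtype)
    padded[half : half + h, half : half + w] = img
    grid = dense.forward(padded / 255.0)
    gh, gw = grid.shape
    s = dense.stride
    iy = np.clip(np.rint(np.arange(h) / s).astype(int), 0, gh - 1)
    ix = np.clip(np.rint(np.arange(w) / s).astype(int), 0, gw - 1)
    values = grid[np.ix_(iy, ix)].astype(np.float32)
    values = np.clip(values, 0.0, 1.0)
    values[~tissue.astype_bool()] = 0.0
    return LikelihoodMap(
        values=values, microns_per_pixel=target_mpp, slide_id=slide.slide_id
    )
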