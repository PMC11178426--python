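"""Training and applying the Tumnet classifier.

The model consumes 227x227 grayscale slices (fused MRI-CT or a single
modality), zero-centers them against the training-set mean image, and
runs the convolutional stack defined in :mod:`tumnet.architecture`.
Training uses softmax cross-entropy with SGD-momentum on a 70/30
train/validation split; all randomness is derived from one seed.

Defaults that the published description leaves open (optimizer,
learning rate, batch size, epochs) are surfaced in :class:`TrainConfig`
and recorded with the saved model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import engine
from .architecture import ArchitectureSpec, build_tumnet
from .image import GrayImage


@dataclass
class TrainConfig:
    """Hyperparameters for Tumnet training.

    learning_rate/momentum/batch_size/epochs are conventional SGD
    settings; dropout 0.6 and the 70/30 split are the model's stated
    regime. ``rng_seed`` drives weight init, shuffling, and dropout.
    """

    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 0.01
    momentum: float = 0.9
    validation_fraction: float = 0.30
    dropout_rate: float = 0.6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class ClassificationResult:
    """Predicted label plus the full softmax distribution."""

    label: str
    probabilities: dict[str, float]


@dataclass(frozen=True)
class FeatureMaps:
    """Per-channel activation maps of one layer, channels first (C, H, W)."""

    layer_name: str
    maps: np.ndarray
    strongest_channel: int


def _build_engine_layers(
    spec: ArchitectureSpec, rng: np.random.Generator
) -> list[tuple[str, engine.Layer]]:
    """Instantiate engine layers named after the architecture rows.

    Flatten and dropout sit between relu_5 and fc; they carry no
    learnables and are bookkeeping-only names.
    """
    layers: list[tuple[str, engine.Layer]] = []
    for ls in spec.layers:
        if ls.kind == "conv":
            layers.append((ls.name, engine.Conv3x3Same(ls.in_channels, ls.out_channels, rng)))
        elif ls.kind == "batchnorm":
            layers.append((ls.name, engine.BatchNorm(ls.out_channels)))
        elif ls.kind == "relu":
            layers.append((ls.name, engine.ReLU()))
        elif ls.kind == "maxpool":
            layers.append((ls.name, engine.MaxPool2x2()))
        elif ls.kind == "fc":
            layers.append(("flatten", engine.Flatten()))
            layers.append(("dropout", engine.Dropout(spec.dropout_rate, rng)))
            layers.append((ls.name, engine.Dense(ls.in_channels, ls.out_channels, rng)))
    return layers


class TumnetModel:
    """A (possibly trained) Tumnet network.

    Use :func:`train` to fit one, or :meth:`load` to restore from disk.
    """

    def __init__(
        self,
        spec: ArchitectureSpec,
        class_names: list[str],
        rng: np.random.Generator | None = None,
    ):
        if spec.num_classes != len(class_names):
            raise ValueError("num_classes must match len(class_names)")
        self.spec = spec
        self.class_names = list(class_names)
        rng = rng if rng is not None else np.random.default_rng(0)
        self.layers = _build_engine_layers(spec, rng)
        h, w, _ = spec.input_shape
        self.mean_image = np.zeros((h, w), dtype=np.float32)
        self.history: dict[str, list[float]] = {}
        self.config: TrainConfig | None = None

    # ------------------------------------------------------------------ io
    def _check_input(self, img: GrayImage) -> None:
        h, w, _ = self.spec.input_shape
        if img.shape != (h, w):
            raise ValueError(
                f"model expects {h}x{w} input, got {img.shape[0]}x{img.shape[1]}"
            )

    def _prepare_batch(self, arrays: np.ndarray) -> np.ndarray:
        x = arrays.astype(np.float32) - self.mean_image
        return x[..., None]

    def _forward(
        self, x: np.ndarray, train: bool, capture: str | None = None
    ) -> np.ndarray:
        captured = None
        for name, layer in self.layers:
            x = layer.forward(x, train)
            if name == capture:
                captured = x
        if capture is not None:
            if capture == "input":
                raise KeyError("feature maps are defined for layers after the input")
            if captured is None:
                raise KeyError(f"no layer named {capture!r}")
            return captured
        return x

    def _backward(self, dout: np.ndarray) -> None:
        for _, layer in reversed(self.layers):
            dout = layer.backward(dout)

    # ------------------------------------------------------------- inference
    def predict_proba(self, imgs: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Softmax probabilities for a stack of raw (N, H, W) intensity arrays."""
        probs = []
        for start in range(0, len(imgs), batch_size):
            x = self._prepare_batch(imgs[start : start + batch_size])
            probs.append(engine.softmax(self._forward(x, train=False)))
        return np.concatenate(probs, axis=0)

    def classify(self, img: GrayImage) -> ClassificationResult:
        """Classify one slice; probabilities sum to 1 and label = argmax."""
        self._check_input(img)
        p = self.predict_proba(img.pixels[None, :, :])[0]
        idx = int(np.argmax(p))
        return ClassificationResult(
            label=self.class_names[idx],
            probabilities={c: float(v) for c, v in zip(self.class_names, p)},
        )

    def feature_maps(self, img: GrayImage, layer_name: str) -> FeatureMaps:
        """Activation maps of a named layer for one input slice.

        The strongest channel is the one with maximal summed absolute
        activation.
        """
        self._check_input(img)
        x = self._prepare_batch(img.pixels[None, :, :])
        act = self._forward(x, train=False, capture=layer_name)[0]
        if act.ndim == 1:  # FC-stage layers: one value per channel
            maps = act.reshape(-1, 1, 1)
        else:
            maps = np.moveaxis(act, -1, 0)
        strongest = int(np.argmax(np.abs(maps).sum(axis=(1, 2))))
        return FeatureMaps(layer_name=layer_name, maps=maps, strongest_channel=strongest)

    # ------------------------------------------------------------ persistence
    def save(self, directory: str | Path) -> None:
        """Save architecture, weights, mean image, config, and history."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "num_classes": self.spec.num_classes,
            "dropout_rate": self.spec.dropout_rate,
            "class_names": self.class_names,
            "config": asdict(self.config) if self.config else None,
            "history": self.history,
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))
        state = {"mean_image": self.mean_image}
        for name, layer in self.layers:
            for key, arr in layer.state_arrays().items():
                state[f"{name}:{key}"] = arr
        np.savez(directory / "weights.npz", **state)

    @classmethod
    def load(cls, directory: str | Path) -> "TumnetModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        spec = build_tumnet(meta["num_classes"], meta["dropout_rate"])
        model = cls(spec, meta["class_names"])
        model.history = meta.get("history", {})
        if meta.get("config"):
            model.config = TrainConfig(**meta["config"])
        with np.load(directory / "weights.npz") as state:
            model.mean_image[...] = state["mean_image"]
            for name, layer in model.layers:
                own = layer.state_arrays()
                layer.load_state(
                    {k: state[f"{name}:{k}"] for k in own if f"{name}:{k}" in state}
                )
        return model


def _as_array_stack(images, input_shape) -> np.ndarray:
    h, w, _ = input_shape
    arrays = []
    for i, img in enumerate(images):
        pix = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=float)
        if pix.shape != (h, w):
            raise ValueError(
                f"image {i} has shape {pix.shape}, model expects ({h}, {w})"
            )
        arrays.append(pix)
    return np.stack(arrays)


def train_validation_split(
    n: int, validation_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Shuffled (train_idx, val_idx) with round(n * fraction) validation
    samples — e.g. 70/30 for n=100, fraction=0.3."""
    order = rng.permutation(n)
    n_val = int(round(n * validation_fraction))
    return order[n_val:], order[:n_val]


def train(
    spec: ArchitectureSpec,
    images,
    labels,
    cfg: TrainConfig | None = None,
) -> TumnetModel:
    """Fit Tumnet on labelled slices.

    ``images`` is a sequence of 227x227 :class:`GrayImage` (or arrays);
    ``labels`` a parallel sequence of class names. The data are split
    70/30 (per ``cfg.validation_fraction``) into training and validation
    sets; the zero-center mean image is computed on the training portion
    only. Returns the trained model with per-epoch loss/accuracy history
    for both splits. Deterministic for a fixed ``cfg.rng_seed``.
    """
    cfg = cfg if cfg is not None else TrainConfig()
    class_names = sorted(set(labels))
    if len(class_names) < 2:
        raise ValueError("training requires at least two classes present")
    if spec.num_classes != len(class_names):
        raise ValueError(
            f"architecture has {spec.num_classes} classes but data has "
            f"{len(class_names)}"
        )
    if spec.dropout_rate != cfg.dropout_rate:
        spec = build_tumnet(spec.num_classes, cfg.dropout_rate)

    x_all = _as_array_stack(images, spec.input_shape)
    y_all = np.array([class_names.index(l) for l in labels], dtype=np.int64)

    rng = np.random.default_rng(cfg.rng_seed)
    n = len(x_all)
    train_idx, val_idx = train_validation_split(n, cfg.validation_fraction, rng)
    if len(val_idx) < 1 or len(train_idx) < 2:
        raise ValueError(f"dataset of {n} images is too small for the requested split")
    if len(set(y_all[train_idx].tolist())) < 2:
        raise ValueError("training split ended up single-class; provide more data")

    model = TumnetModel(spec, class_names, rng=rng)
    model.config = cfg
    model.mean_image[...] = x_all[train_idx].mean(axis=0).astype(np.float32)

    opt = engine.SGDMomentum(
        [layer for _, layer in model.layers], cfg.learning_rate, cfg.momentum
    )
    history: dict[str, list[float]] = {
        "train_loss": [], "train_accuracy": [],
        "val_loss": [], "val_accuracy": [],
    }

    def _eval(idx: np.ndarray) -> tuple[float, float]:
        losses, hits, total = [], 0, 0
        for s in range(0, len(idx), 32):
            chunk = idx[s : s + 32]
            x = model._prepare_batch(x_all[chunk])
            logits = model._forward(x, train=False)
            loss, _ = engine.softmax_cross_entropy(logits, y_all[chunk])
            losses.append(loss * len(chunk))
            hits += int((logits.argmax(axis=1) == y_all[chunk]).sum())
            total += len(chunk)
        return sum(losses) / total, hits / total

    for _ in range(cfg.epochs):
        perm = train_idx[rng.permutation(len(train_idx))]
        epoch_loss, epoch_hits = 0.0, 0
        for s in range(0, len(perm), cfg.batch_size):
            chunk = perm[s : s + cfg.batch_size]
            x = model._prepare_batch(x_all[chunk])
            logits = model._forward(x, train=True)
            loss, dlogits = engine.softmax_cross_entropy(logits, y_all[chunk])
            model._backward(dlogits)
            opt.step()
            epoch_loss += loss * len(chunk)
            epoch_hits += int((logits.argmax(axis=1) == y_all[chunk]).sum())
        history["train_loss"].append(epoch_loss / len(perm))
        history["train_accuracy"].append(epoch_hits / len(perm))
        val_loss, val_acc = _eval(val_idx)
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)

    model.history = history
    return model


def evaluate(model: TumnetModel, images, labels) -> float:
    """Fraction of slices whose predicted label matches the given label."""
    x = _as_array_stack(images, model.spec.input_shape)
    probs = model.predict_proba(x)
    predicted = [model.class_names[int(i)] for i in probs.argmax(axis=1)]
    return float(np.mean([p == t for p, t in zip(predicted, labels)]))
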