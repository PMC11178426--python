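"""Tumnet architecture: layer table, shape arithmetic, parameter accounting.

Tumnet is a small CNN for tumor/no-tumor slice classification: five 3x3
convolution stages (8, 16, 32, 64, 128 channels), each followed by batch
normalization and ReLU, with 2x2/stride-2 max pooling after the first
four stages, then a single fully connected layer feeding a softmax. The
227x227x1 input passes through activation shapes
227 -> 113 -> 56 -> 28 -> 14, flattening to 14*14*128 = 25088 features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Flattened feature length entering the fully connected layer.
FLATTEN_LENGTH = 14 * 14 * 128

INPUT_SHAPE = (227, 227, 1)

#: Output channels of the five convolution stages.
CONV_CHANNELS = (8, 16, 32, 64, 128)


@dataclass(frozen=True)
class LayerSpec:
    """One row of the architecture table."""

    name: str
    kind: str  # input | conv | batchnorm | relu | maxpool | fc | softmax | classification_output
    activation_shape: tuple[int, ...]
    kernel: tuple[int, int] | None = None
    in_channels: int | None = None
    out_channels: int | None = None
    stride: tuple[int, int] | None = None
    padding: str | None = None


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer sequence plus global settings."""

    layers: tuple[LayerSpec, ...]
    num_classes: int
    input_shape: tuple[int, int, int] = INPUT_SHAPE
    dropout_rate: float = 0.6

    def layer(self, name: str) -> LayerSpec:
        for ls in self.layers:
            if ls.name == name:
                return ls
        raise KeyError(f"no layer named {name!r}")

    @property
    def layer_names(self) -> tuple[str, ...]:
        return tuple(ls.name for ls in self.layers)


def relu(x):
    """Rectified linear unit: max(0, x), elementwise on arrays."""
    return np.maximum(0, x)


def pooled_output_size(
    n_h: int, n_w: int, n_c: int, f: int, s: int
) -> tuple[int, int, int]:
    """Output shape of an f x f / stride-s pooling window on (n_h, n_w, n_c).

    h = floor((n_h - f) / s) + 1 and likewise for w; channels pass
    through. With f=2, s=2 this maps 227 -> 113, 113 -> 56, 56 -> 28,
    28 -> 14.
    """
    if s < 1:
        raise ValueError(f"stride must be >= 1, got {s}")
    if f > n_h or f > n_w:
        raise ValueError(f"pool window {f} exceeds input extent ({n_h}, {n_w})")
    return ((n_h - f) // s + 1, (n_w - f) // s + 1, n_c)


def build_tumnet(num_classes: int = 2, dropout_rate: float = 0.6) -> ArchitectureSpec:
    """Construct the Tumnet layer sequence.

    ``num_classes`` sizes the fully connected / softmax head (2 for the
    tumor vs. no-tumor task; 6 reproduces the published parameter table).
    Dropout (default 0.6) acts between flattening and the FC layer during
    training only. The input layer applies zero-center normalization:
    the training-set mean image is subtracted from every input.
    """
    if num_classes < 2:
        raise ValueError(f"num_classes must be >= 2, got {num_classes}")
    if not 0 <= dropout_rate < 1:
        raise ValueError(f"dropout_rate must be in [0, 1), got {dropout_rate}")

    layers: list[LayerSpec] = []
    h, w = INPUT_SHAPE[:2]
    c_in = INPUT_SHAPE[2]
    layers.append(LayerSpec("input", "input", (h, w, c_in)))
    for i, c_out in enumerate(CONV_CHANNELS, start=1):
        layers.append(
            LayerSpec(
                f"conv_{i}", "conv", (h, w, c_out),
                kernel=(3, 3), in_channels=c_in, out_channels=c_out,
                stride=(1, 1), padding="same",
            )
        )
        layers.append(
            LayerSpec(f"batchnorm_{i}", "batchnorm", (h, w, c_out),
                      in_channels=c_out, out_channels=c_out)
        )
        layers.append(LayerSpec(f"relu_{i}", "relu", (h, w, c_out)))
        if i < 5:  # four pooling stages; the fifth conv block feeds the FC head
            h, w, _ = pooled_output_size(h, w, c_out, f=2, s=2)
            layers.append(
                LayerSpec(
                    f"maxpool_{i}", "maxpool", (h, w, c_out),
                    kernel=(2, 2), stride=(2, 2), padding="zero-explicit",
                )
            )
        c_in = c_out
    layers.append(
        LayerSpec("fc", "fc", (1, 1, num_classes),
                  in_channels=FLATTEN_LENGTH, out_channels=num_classes)
    )
    layers.append(LayerSpec("softmax", "softmax", (1, 1, num_classes)))
    layers.append(
        LayerSpec("classification_output", "classification_output",
                  (1, 1, num_classes))
    )
    return ArchitectureSpec(
        layers=tuple(layers), num_classes=num_classes, dropout_rate=dropout_rate
    )


def count_learnables(spec: ArchitectureSpec) -> dict[str, int]:
    """Learnable-parameter count per layer, plus a ``"total"`` entry.

    conv: kh*kw*c_in*c_out weights + c_out biases; batchnorm: offset and
    scale per channel (2*c); fc: classes*flatten weights + classes
    biases; all other layers learn nothing.
    """
    counts: dict[str, int] = {}
    for ls in spec.layers:
        if ls.kind == "conv":
            kh, kw = ls.kernel
            counts[ls.name] = kh * kw * ls.in_channels * ls.out_channels + ls.out_channels
        elif ls.kind == "batchnorm":
            counts[ls.name] = 2 * ls.out_channels
        elif ls.kind == "fc":
            counts[ls.name] = ls.out_channels * ls.in_channels + ls.out_channels
        else:
            counts[ls.name] = 0
    counts["total"] = sum(counts.values())
    return counts
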