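"""Declarative architecture specs, shape propagation and the 3D conv primitive.

Two architectures are described here as ordered layer-spec lists:

* **BufferNet** — a 3D spectral-spatial classifier for ``200 x 9 x 9``
  spectral samples.  A stem convolution (spectral kernel 5, spatial
  kernel 1, stride (2,1,1)) halves the spectral axis to 98 x 9 x 9 / 64
  channels, followed by three *buffer blocks*: one down-sampling conv
  (kernel 3, stride 2, padding 1) then three buffer convs (stride 1,
  padding 1) each, with 64 / 128 / 256 output channels.  That makes 13
  3D conv layers in total, each followed by 3D batch normalization;
  average pooling (kernel 2, stride 2, floor) then a dense layer emit
  two class logits.  The printed feature-map chain is
  98x9x9 -> 49x5x5 -> 25x3x3 -> 13x2x2 -> 6x1x1.
* **VGG-16** — the standard 5-block 2D backbone (2,2,3,3,3 convs of
  3x3; five 2x2 max pools; three dense layers) used as the transfer
  backbone, its head replaceable for the binary task.

Specs are data, not code: ``propagate_shapes`` and ``count_parameters``
audit them, and ``build_network`` materializes them as trainable
numpy layers (inserting ReLU after each normalization / hidden dense).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .errors import ShapeError

__all__ = [
    "LayerSpec",
    "ShapeTrace",
    "buffernet_spec",
    "vgg16_spec",
    "propagate_shapes",
    "count_parameters",
    "conv3d_forward",
    "build_network",
]

LAYER_KINDS = {
    "conv3d", "batchnorm3d", "avgpool3d", "conv2d", "maxpool2d", "dense", "softmax",
}


@dataclass
class LayerSpec:
    """One layer of an architecture; conv axes ordered (spectral, H, W)."""

    name: str
    kind: str
    kernel: tuple[int, ...] = ()
    stride: tuple[int, ...] = ()
    padding: tuple[int, ...] = ()
    channels_in: int = 0
    channels_out: int = 0
    features_in: int = 0  # dense layers only
    block: int = 0  # transfer-learning block tag; 0 = stem/head
    trainable: bool = True

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind.startswith("conv"):
            if min(self.kernel) < 1 or min(self.stride) < 1 or min(self.padding) < 0:
                raise ValueError(f"{self.name}: bad kernel/stride/padding")


@dataclass
class ShapeTrace:
    """Ordered (layer name, output extents, channels) trace."""

    entries: list[tuple[str, tuple[int, ...], int]] = field(default_factory=list)

    def after(self, name: str) -> tuple[tuple[int, ...], int]:
        for entry in self.entries:
            if entry[0] == name:
                return entry[1], entry[2]
        raise KeyError(name)

    def final(self) -> tuple[tuple[int, ...], int]:
        name, extents, channels = self.entries[-1]
        return extents, channels


def _conv_extent(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


def propagate_shapes(
    spec: list[LayerSpec],
    input_extents: tuple[int, ...],
    input_channels: int = 1,
) -> ShapeTrace:
    """Propagate feature-map extents through a spec.

    Conv layers follow ``floor((n + 2p - k) / s) + 1`` per axis; pooling
    layers (kernel == stride) follow ``floor(n / k)``.  Any extent
    dropping below 1 raises a ShapeError naming the layer.
    """
    extents = tuple(int(e) for e in input_extents)
    channels = input_channels
    trace = ShapeTrace()
    for layer in spec:
        if layer.kind in ("conv3d", "conv2d"):
            extents = tuple(
                _conv_extent(n, k, s, p)
                for n, k, s, p in zip(extents, layer.kernel, layer.stride, layer.padding)
            )
            channels = layer.channels_out
        elif layer.kind in ("avgpool3d", "maxpool2d"):
            # floor-mode pooling; kernels clip to axes shorter than them
            extents = tuple(n // min(k, n) for n, k in zip(extents, layer.kernel))
        elif layer.kind == "dense":
            extents = ()
            channels = layer.channels_out
        # batchnorm3d / softmax leave shape untouched
        if extents and min(extents) < 1:
            raise ShapeError(f"layer {layer.name!r} output extent {extents} < 1")
        trace.entries.append((layer.name, extents, channels))
    return trace


def buffernet_spec(
    in_bands: int = 200,
    window: int = 9,
    base_channels: int = 64,
) -> list[LayerSpec]:
    """BufferNet: 13 3D convs (1 stem + 3 blocks of 1 down + 3 buffer).

    Block output channels are ``base_channels`` x (1, 2, 4) — 64, 128,
    256 at full width.  ``base_channels`` scales the network's width for
    desk-scale runs without changing its shape chain.
    """
    if in_bands < 16:
        raise ValueError("in_bands must be >= 16")
    spec: list[LayerSpec] = []

    def conv(name, cin, cout, kernel, stride, padding, block):
        spec.append(LayerSpec(name, "conv3d", kernel, stride, padding,
                              channels_in=cin, channels_out=cout, block=block))
        spec.append(LayerSpec(name + ".bn", "batchnorm3d",
                              channels_in=cout, channels_out=cout, block=block))

    conv("stem", 1, base_channels, (5, 1, 1), (2, 1, 1), (0, 0, 0), block=0)
    channels = base_channels
    for b, mult in enumerate((1, 2, 4), start=1):
        cout = base_channels * mult
        conv(f"block{b}.down", channels, cout, (3, 3, 3), (2, 2, 2), (1, 1, 1), block=b)
        for j in range(1, 4):
            conv(f"block{b}.buffer{j}", cout, cout, (3, 3, 3), (1, 1, 1), (1, 1, 1), block=b)
        channels = cout
    spec.append(LayerSpec("avgpool", "avgpool3d", kernel=(2, 2, 2), stride=(2, 2, 2)))

    trace = propagate_shapes(spec, (in_bands, window, window), input_channels=1)
    extents, ch = trace.final()
    spec.append(LayerSpec("head", "dense", features_in=ch * int(np.prod(extents)),
                          channels_out=2))
    spec.append(LayerSpec("softmax", "softmax", channels_in=2, channels_out=2))
    return spec


def vgg16_spec(
    head_classes: int = 2,
    base_channels: int = 64,
    input_size: int = 250,
    head_hidden: tuple[int, ...] = (4096, 4096),
) -> list[LayerSpec]:
    """The standard VGG-16 arrangement with a replaceable dense head.

    Five conv blocks of (2, 2, 3, 3, 3) 3x3 convs with channels
    64/128/256/512/512 (at full width), a 2x2 max pool after each block
    — 13 conv layers and 5 pooling layers — then three dense layers.
    ``base_channels``, ``input_size`` and ``head_hidden`` scale the
    backbone for desk-scale transfer experiments.
    """
    plan = [(1, 2, 1), (2, 2, 2), (3, 3, 4), (4, 3, 8), (5, 3, 8)]
    spec: list[LayerSpec] = []
    channels = 3
    for block, n_convs, mult in plan:
        cout = base_channels * mult
        for j in range(1, n_convs + 1):
            spec.append(LayerSpec(f"block{block}.conv{j}", "conv2d", (3, 3), (1, 1), (1, 1),
                                  channels_in=channels, channels_out=cout, block=block))
            channels = cout
        spec.append(LayerSpec(f"block{block}.pool", "maxpool2d",
                              kernel=(2, 2), stride=(2, 2), block=block))
    trace = propagate_shapes(spec, (input_size, input_size), input_channels=3)
    extents, ch = trace.final()
    features = ch * int(np.prod(extents))
    for i, width in enumerate(head_hidden, start=1):
        spec.append(LayerSpec(f"fc{i}", "dense", features_in=features, channels_out=width))
        features = width
    spec.append(LayerSpec("head", "dense", features_in=features, channels_out=head_classes))
    spec.append(LayerSpec("softmax", "softmax",
                          channels_in=head_classes, channels_out=head_classes))
    return spec


def count_parameters(spec: list[LayerSpec]) -> int:
    """Weights + biases: conv = prod(k)*Cin*Cout + Cout; BN = 2C; dense = in*out + out."""
    total = 0
    for layer in spec:
        if layer.kind in ("conv3d", "conv2d"):
            total += int(np.prod(layer.kernel)) * layer.channels_in * layer.channels_out
            total += layer.channels_out
        elif layer.kind == "batchnorm3d":
            total += 2 * layer.channels_out
        elif layer.kind == "dense":
            total += layer.features_in * layer.channels_out + layer.channels_out
    return total


def conv3d_forward(
    data: np.ndarray,
    kernel: np.ndarray,
    stride: int | tuple[int, int, int] = 1,
    padding: int | tuple[int, int, int] = 0,
) -> np.ndarray:
    """Direct 3D sliding-window convolution (cross-correlation form).

    ``data`` is ``(S, H, W)`` single-channel or ``(C_in, S, H, W)``;
    ``kernel`` is ``(K, I, J)`` or ``(C_out, C_in, K, I, J)``.  The
    multi-channel form sums over input channels.  Output extent per axis
    is ``floor((n + 2p - k) / s) + 1``.
    """
    data = np.asarray(data, dtype=np.float64)
    kernel = np.asarray(kernel, dtype=np.float64)
    single_in = data.ndim == 3
    single_out = kernel.ndim == 3
    if single_in:
        data = data[None]
    if single_out:
        kernel = kernel[None, None]
    if kernel.shape[1] != data.shape[0]:
        raise ValueError("kernel input channels do not match data channels")
    stride = (stride,) * 3 if np.isscalar(stride) else tuple(stride)
    padding = (padding,) * 3 if np.isscalar(padding) else tuple(padding)
    if any(padding):
        data = np.pad(data, [(0, 0)] + [(p, p) for p in padding])
    out_ext = tuple(
        (n - k) // s + 1 for n, k, s in zip(data.shape[1:], kernel.shape[2:], stride)
    )
    if min(out_ext) < 1:
        raise ShapeError(
            f"kernel {kernel.shape[2:]} larger than padded input {data.shape[1:]}"
        )
    windows = np.lib.stride_tricks.sliding_window_view(data, kernel.shape[2:], axis=(1, 2, 3))
    windows = windows[:, :: stride[0], :: stride[1], :: stride[2]]  # (Cin,S',H',W',K,I,J)
    out = np.tensordot(kernel, windows, axes=([1, 2, 3, 4], [0, 4, 5, 6]))
    return out[0] if single_out else out


def build_network(spec: list[LayerSpec], rng: np.random.Generator | int = 0) -> nn.Network:
    """Materialize a spec as a trainable numpy network emitting logits.

    ReLU is inserted after every batch-normalization layer, after bare
    2D convs (the VGG arrangement) and after hidden dense layers; the
    softmax spec entry maps to the loss side, so the network itself
    returns logits.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    layers: list[nn.Layer] = []
    flattened = False
    dense_specs = [l for l in spec if l.kind == "dense"]
    for i, ls in enumerate(spec):
        nxt = spec[i + 1] if i + 1 < len(spec) else None
        if ls.kind == "conv3d":
            layer = nn.Conv3d(ls.channels_in, ls.channels_out, ls.kernel,
                              ls.stride, ls.padding, rng=rng, name=ls.name)
        elif ls.kind == "conv2d":
            layer = nn.Conv2d(ls.channels_in, ls.channels_out, ls.kernel,
                              ls.stride, ls.padding, rng=rng, name=ls.name)
        elif ls.kind == "batchnorm3d":
            layer = nn.BatchNorm(ls.channels_out, name=ls.name)
        elif ls.kind == "avgpool3d":
            layer = nn.AvgPool3d(ls.kernel)
        elif ls.kind == "maxpool2d":
            layer = nn.MaxPool2d(ls.kernel)
        elif ls.kind == "dense":
            if not flattened:
                layers.append(nn.Flatten())
                flattened = True
            layer = nn.Dense(ls.features_in, ls.channels_out, rng=rng, name=ls.name)
        elif ls.kind == "softmax":
            continue  # handled by the cross-entropy loss / predict_proba
        layer.block = ls.block
        for p in layer.params():
            p.trainable = ls.trainable
        layers.append(layer)
        if ls.kind == "batchnorm3d":
            layers.append(nn.ReLU())
        elif ls.kind == "conv2d" and (nxt is None or nxt.kind != "batchnorm3d"):
            layers.append(nn.ReLU())
        elif ls.kind == "dense" and ls is not dense_specs[-1]:
            layers.append(nn.ReLU())
    return nn.Network(layers)


def spec_to_json(spec: list[LayerSpec]) -> str:
    return json.dumps([asdict(l) for l in spec], indent=1)


def spec_from_json(text: str) -> list[LayerSpec]:
    raw = json.loads(text)
    out = []
    for d in raw:
        for key in ("kernel", "stride", "padding"):
            d[key] = tuple(d[key])
        out.append(LayerSpec(**d))
    return out
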