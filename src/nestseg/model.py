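"""The nest-segmentation convolutional autoencoder.

A fixed 128x128x3 input is compressed by three conv/conv/max-pool stages to a
16x16x64 latent code and expanded back by conv stacks interleaved with
nearest-neighbour upsampling.  Two heads are supported:

* ``reconstruction`` — final 3x3 conv with 3 channels and ReLU, trained with
  mean squared error to reproduce the input patch;
* ``segmentation`` — final 3x3 conv with 1 channel and sigmoid, trained with
  binary cross-entropy to emit a per-pixel nest probability map.

The two variants share every layer except that last convolution, which is
what makes encoder transfer between them well defined.  The hidden channel
progression is 32, 64 | 64, 128 | 128, 64 (encoder) and 64, 32, 32, 64 | 64,
128 | 128, 64 | 64, 32 (decoder): 16 hidden conv layers plus three pools and
three upsamples (22 hidden layers), 822,529 trainable parameters with the
segmentation head.
"""

from __future__ import annotations

import copy
import io
import json
from dataclasses import dataclass, field

import numpy as np

from ._nn import BufferPool, Conv2DSame, MaxPool2, Upsample2

INPUT_SHAPE = (128, 128, 3)

#: hidden conv output channels, in order; pools sit after hidden convs 2, 4, 6
#: and upsamples after hidden convs 10, 12, 14
_HIDDEN_CHANNELS = (32, 64, 64, 128, 128, 64, 64, 32, 32, 64, 64, 128, 128, 64, 64, 32)
_POOL_AFTER = frozenset({2, 4, 6})
_UPSAMPLE_AFTER = frozenset({10, 12, 14})

VARIANTS = ("reconstruction", "segmentation")


class ContractError(ValueError):
    """Raised when a model/operation contract is violated."""


@dataclass(frozen=True)
class LayerSpec:
    """One layer row of the architecture summary."""

    name: str
    kind: str  # conv | maxpool | upsample
    out_channels: int | None
    kernel: int
    activation: str  # relu | sigmoid | none
    padding: str  # 'same' for conv, '' otherwise


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer list plus the encoder/decoder boundary.

    ``encoder_end_index`` is the index of the last encoder layer (the third
    max-pool, whose output is the 16x16x64 code).
    """

    layers: tuple[LayerSpec, ...]
    variant: str
    encoder_end_index: int
    input_shape: tuple[int, int, int] = INPUT_SHAPE

    def output_shapes(self) -> list[tuple[int, int, int]]:
        """Per-layer output (H, W, C) for the canonical 128x128x3 input."""
        h, w, c = self.input_shape
        shapes = []
        for layer in self.layers:
            if layer.kind == "conv":
                c = layer.out_channels
            elif layer.kind == "maxpool":
                h, w = h // 2, w // 2
            elif layer.kind == "upsample":
                h, w = h * 2, w * 2
            shapes.append((h, w, c))
        return shapes


def build_architecture(variant: str) -> ArchitectureSpec:
    """Construct the canonical layer list for either head variant."""
    if variant not in VARIANTS:
        raise ContractError(f"variant must be one of {VARIANTS}, got {variant!r}")
    layers: list[LayerSpec] = []
    n_conv = n_pool = n_up = 0

    def conv_name() -> str:
        nonlocal n_conv
        name = "conv2d" if n_conv == 0 else f"conv2d_{n_conv}"
        n_conv += 1
        return name

    encoder_end = -1
    for i, ch in enumerate(_HIDDEN_CHANNELS, start=1):
        layers.append(LayerSpec(conv_name(), "conv", ch, 3, "relu", "same"))
        if i in _POOL_AFTER:
            name = "max_pooling2d" if n_pool == 0 else f"max_pooling2d_{n_pool}"
            n_pool += 1
            layers.append(LayerSpec(name, "maxpool", None, 2, "none", ""))
            if i == max(_POOL_AFTER):
                encoder_end = len(layers) - 1
        if i in _UPSAMPLE_AFTER:
            name = "up_sampling2d" if n_up == 0 else f"up_sampling2d_{n_up}"
            n_up += 1
            layers.append(LayerSpec(name, "upsample", None, 2, "none", ""))
    if variant == "segmentation":
        layers.append(LayerSpec(conv_name(), "conv", 1, 3, "sigmoid", "same"))
    else:
        layers.append(LayerSpec(conv_name(), "conv", 3, 3, "relu", "same"))
    return ArchitectureSpec(tuple(layers), variant, encoder_end)


def _conv_params(c_in: int, c_out: int) -> int:
    return (3 * 3 * c_in + 1) * c_out


def count_parameters(spec: ArchitectureSpec, scope: str = "all"):
    """Trainable parameter count, overall or per section.

    ``scope='per_layer'`` returns an ordered ``{name: count}`` dict; the
    other scopes return an integer.
    """
    c_in = spec.input_shape[2]
    per_layer: dict[str, int] = {}
    encoder_total = decoder_total = 0
    for i, layer in enumerate(spec.layers):
        n = 0
        if layer.kind == "conv":
            n = _conv_params(c_in, layer.out_channels)
            c_in = layer.out_channels
        per_layer[layer.name] = n
        if i <= spec.encoder_end_index:
            encoder_total += n
        else:
            decoder_total += n
    if scope == "per_layer":
        return per_layer
    if scope == "encoder":
        return encoder_total
    if scope == "decoder":
        return decoder_total
    if scope == "all":
        return encoder_total + decoder_total
    raise ContractError(f"unknown scope {scope!r}")


def summary(spec: ArchitectureSpec) -> str:
    """Keras-style architecture table: layer name/type, output shape, params."""
    rows = [("input_1 (InputLayer)", f"[(None, {', '.join(map(str, spec.input_shape))})]", 0)]
    kinds = {"conv": "Conv2D", "maxpool": "MaxPooling2D", "upsample": "UpSampling2D"}
    counts = count_parameters(spec, "per_layer")
    for layer, (h, w, c) in zip(spec.layers, spec.output_shapes()):
        rows.append(
            (f"{layer.name} ({kinds[layer.kind]})", f"(None, {h}, {w}, {c})",
             counts[layer.name])
        )
    total = count_parameters(spec, "all")
    buf = io.StringIO()
    buf.write(f"{'Layer (type)':<34}{'Output Shape':<26}{'Param #':>10}\n")
    buf.write("=" * 70 + "\n")
    for name, shape, n in rows:
        buf.write(f"{name:<34}{shape:<26}{n:>10,}\n")
    buf.write("=" * 70 + "\n")
    buf.write(f"Total params: {total:,}\n")
    buf.write(f"Trainable params: {total:,}\n")
    buf.write("Non-trainable params: 0\n")
    return buf.getvalue()


@dataclass
class CAEModel:
    """Architecture spec bound to concrete layer objects holding weights."""

    spec: ArchitectureSpec
    layers: list = field(default_factory=list)

    @classmethod
    def from_spec(cls, spec: ArchitectureSpec) -> "CAEModel":
        pool = BufferPool()  # one shared workspace per model
        layers = []
        c_in = spec.input_shape[2]
        for ls in spec.layers:
            if ls.kind == "conv":
                layers.append(
                    Conv2DSame(ls.name, c_in, ls.out_channels, ls.activation, pool)
                )
                c_in = ls.out_channels
            elif ls.kind == "maxpool":
                layers.append(MaxPool2(ls.name, pool))
            else:
                layers.append(Upsample2(ls.name, pool))
        return cls(spec, layers)

    # -- weight access -----------------------------------------------------
    @property
    def conv_layers(self):
        return [l for l in self.layers if l.kind == "conv"]

    def encoder_layers(self):
        return self.layers[: self.spec.encoder_end_index + 1]

    def decoder_layers(self):
        return self.layers[self.spec.encoder_end_index + 1 :]

    @property
    def frozen_flags(self) -> list[bool]:
        return [l.frozen for l in self.layers]

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for l in self.conv_layers:
            out[f"{l.name}.W"] = l.W.copy()
            out[f"{l.name}.b"] = l.b.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for l in self.conv_layers:
            l.W = state[f"{l.name}.W"].astype(np.float32).copy()
            l.b = state[f"{l.name}.b"].astype(np.float32).copy()

    def copy(self) -> "CAEModel":
        other = CAEModel.from_spec(self.spec)
        other.load_state_dict(self.state_dict())
        for a, b in zip(other.layers, self.layers):
            a.frozen = b.frozen
        return other

    # -- forward -----------------------------------------------------------
    def forward(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        """Run a (N, 128, 128, 3) batch of patches through the network."""
        x = np.asarray(batch, np.float32)
        if x.ndim != 4 or x.shape[1:] != self.spec.input_shape:
            raise ContractError(
                f"expected batch of shape (N, {self.spec.input_shape}), got {x.shape}"
            )
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    __call__ = forward

    def backward(self, d_preact: np.ndarray) -> None:
        """Backprop from the gradient w.r.t. the head's pre-activation.

        Frozen encoders truncate the pass at the encoder boundary: no
        gradients are computed (or applied) for encoder layers.
        """
        stop = 0
        if all(l.frozen for l in self.encoder_layers()):
            stop = self.spec.encoder_end_index + 1
        dy = d_preact
        for i in range(len(self.layers) - 1, stop - 1, -1):
            layer = self.layers[i]
            if layer.kind == "conv":
                dy = layer.backward(
                    dy, need_dx=(i > stop), preact_grad=(i == len(self.layers) - 1)
                )
            else:
                dy = layer.backward(dy)


def initialize(model: CAEModel, seed: int) -> CAEModel:
    """Glorot-uniform conv weights, zero biases, from one seeded generator."""
    rng = np.random.default_rng(seed)
    for layer in model.conv_layers:
        layer.init_glorot(rng)
    return model


def transfer_encoder(source: CAEModel, target_variant: str, seed: int) -> CAEModel:
    """New model of ``target_variant`` with the source's encoder weights copied
    bit-for-bit and every decoder conv re-initialised from ``seed``."""
    target = CAEModel.from_spec(build_architecture(target_variant))
    if source.spec.encoder_end_index != target.spec.encoder_end_index:
        raise ContractError("encoder boundaries differ between source and target")
    rng = np.random.default_rng(seed)
    n_enc = source.spec.encoder_end_index + 1
    for src, dst in zip(source.layers[:n_enc], target.layers[:n_enc]):
        if src.kind == "conv":
            if (src.c_in, src.c_out) != (dst.c_in, dst.c_out):
                raise ContractError(f"encoder layer {src.name} shape mismatch")
            dst.W = src.W.copy()
            dst.b = src.b.copy()
    for layer in target.decoder_layers():
        if layer.kind == "conv":
            layer.init_glorot(rng)
    return target


def set_encoder_frozen(model: CAEModel, frozen: bool) -> CAEModel:
    """Mark every encoder layer (up to and including the code-producing third
    max-pool) as frozen/unfrozen; the trainer leaves frozen weights untouched."""
    for layer in model.encoder_layers():
        layer.frozen = frozen
    return model


# -- checkpoints -----------------------------------------------------------

def save_checkpoint(model: CAEModel, path) -> None:
    """Single ``.npz`` archive: per-layer named tensors + JSON-coded spec."""
    spec_json = json.dumps(
        {
            "variant": model.spec.variant,
            "encoder_end_index": model.spec.encoder_end_index,
            "frozen_flags": model.frozen_flags,
        }
    )
    np.savez(path, __spec__=np.frombuffer(spec_json.encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path) -> CAEModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__spec__"]).decode())
        model = CAEModel.from_spec(build_architecture(meta["variant"]))
        model.load_state_dict({k: data[k] for k in data.files if k != "__spec__"})
    for layer, flag in zip(model.layers, meta["frozen_flags"]):
        layer.frozen = bool(flag)
    return model
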