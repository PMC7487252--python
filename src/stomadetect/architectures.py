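"""Declarative CNN architecture specs and an exact parameter counter.

Three patch classifiers are defined over 120 x 120 x 3 inputs:

* ``basic_shallow`` — three 3x3 valid convolutions of depth 8/16/32, each
  followed by 2x2 max pooling, then two dense layers of 32 units and a
  2-way softmax (180,242 parameters);
* ``basic_deep``    — same topology with conv depths 32/64/128 and dense
  layers of 1,024 units (23,297,090 parameters);
* ``vgg19``         — the standard VGG19 convolutional base (16 conv
  layers, 3x3 'same', five 2x2 pool stages; 20,024,384 parameters, held
  frozen for fine-tuning) with a dense head 4096 → 2048 → 2
  (27,273,218 trainable; 47,297,602 in total).

Parameter counting is pure integer arithmetic over the layer chain — no
ML framework is involved — so the printed totals above are exact
invariants of the specs, checkable anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "TrainingHyperparams",
    "ArchitectureError",
    "basic_shallow",
    "basic_deep",
    "vgg19",
    "get_architecture",
    "count_parameters",
    "resolve_shapes",
    "ARCHITECTURES",
]

LayerKind = Literal[
    "conv3x3_valid", "conv3x3_same", "maxpool2x2",
    "flatten", "dense", "dropout", "softmax_output",
]


class ArchitectureError(ValueError):
    """Raised when a layer chain cannot be resolved into valid shapes."""


@dataclass(frozen=True)
class LayerSpec:
    kind: LayerKind
    channels_or_units: int = 0


@dataclass(frozen=True)
class ArchitectureSpec:
    name: str
    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int] = (120, 120, 3)
    #: number of leading layers whose parameters are not trained
    frozen_prefix: int = 0


def resolve_shapes(spec: ArchitectureSpec) -> list[tuple]:
    """Propagate the input shape through the chain; shape after each layer.

    Conv 'valid' maps (h, w, c) → (h−2, w−2, k); 'same' keeps h, w;
    2x2 max pooling floors halved spatial dims.  Raises
    :class:`ArchitectureError`, naming the offending layer, when the chain
    breaks (e.g. dense before flatten, or a spatial dim collapsing to 0).
    """
    shape: tuple = spec.input_shape
    out = []
    for i, layer in enumerate(spec.layers):
        k = layer.kind
        where = f"layer {i} ({k})"
        if k in ("conv3x3_valid", "conv3x3_same", "maxpool2x2"):
            if len(shape) != 3:
                raise ArchitectureError(f"{where}: expects a (h, w, c) input, got {shape}")
            h, w, c = shape
            if k == "conv3x3_valid":
                shape = (h - 2, w - 2, layer.channels_or_units)
            elif k == "conv3x3_same":
                shape = (h, w, layer.channels_or_units)
            else:
                shape = (h // 2, w // 2, c)
            if shape[0] < 1 or shape[1] < 1:
                raise ArchitectureError(f"{where}: spatial dims collapsed to {shape[:2]}")
        elif k == "flatten":
            if len(shape) != 3:
                raise ArchitectureError(f"{where}: expects a (h, w, c) input, got {shape}")
            shape = (shape[0] * shape[1] * shape[2],)
        elif k in ("dense", "softmax_output"):
            if len(shape) != 1:
                raise ArchitectureError(f"{where}: expects a flat input, got {shape}")
            shape = (layer.channels_or_units,)
        elif k == "dropout":
            pass
        else:  # pragma: no cover - exhaustive kinds
            raise ArchitectureError(f"{where}: unknown layer kind")
        out.append(shape)
    return out


def _layer_params(layer: LayerSpec, in_shape: tuple) -> int:
    k = layer.kind
    if k in ("conv3x3_valid", "conv3x3_same"):
        c_in = in_shape[2]
        return 3 * 3 * c_in * layer.channels_or_units + layer.channels_or_units
    if k in ("dense", "softmax_output"):
        return (in_shape[0] + 1) * layer.channels_or_units
    return 0


def count_parameters(spec: ArchitectureSpec) -> tuple[int, int]:
    """(total, trainable) parameter counts by exact integer arithmetic.

    Convolution: 3·3·c_in·c_out weights + c_out biases; dense layers:
    (n_in + 1)·n_out.  Layers in the frozen prefix contribute to the total
    but not to the trainable count.
    """
    shapes = [spec.input_shape] + resolve_shapes(spec)
    total = trainable = 0
    for i, layer in enumerate(spec.layers):
        n = _layer_params(layer, shapes[i])
        total += n
        if i >= spec.frozen_prefix:
            trainable += n
    return total, trainable


def _basic(name: str, convs: tuple[int, int, int], dense_units: int) -> ArchitectureSpec:
    layers = []
    for c in convs:
        layers += [LayerSpec("conv3x3_valid", c), LayerSpec("maxpool2x2")]
    layers += [
        LayerSpec("flatten"),
        LayerSpec("dense", dense_units),
        LayerSpec("dropout"),
        LayerSpec("dense", dense_units),
        LayerSpec("dropout"),
        LayerSpec("softmax_output", 2),
    ]
    return ArchitectureSpec(name, tuple(layers))


def basic_shallow() -> ArchitectureSpec:
    return _basic("basic_shallow", (8, 16, 32), 32)


def basic_deep() -> ArchitectureSpec:
    return _basic("basic_deep", (32, 64, 128), 1024)


#: conv depths per VGG19 stage: 2x64, 2x128, 4x256, 4x512, 4x512
_VGG19_STAGES = ((64, 64), (128, 128), (256,) * 4, (512,) * 4, (512,) * 4)


def vgg19() -> ArchitectureSpec:
    layers = []
    for stage in _VGG19_STAGES:
        for c in stage:
            layers.append(LayerSpec("conv3x3_same", c))
        layers.append(LayerSpec("maxpool2x2"))
    n_frozen = len(layers)  # the pretrained convolutional base stays fixed
    layers += [
        LayerSpec("flatten"),
        LayerSpec("dense", 4096),
        LayerSpec("dropout"),
        LayerSpec("dense", 2048),
        LayerSpec("dropout"),
        LayerSpec("softmax_output", 2),
    ]
    return ArchitectureSpec("vgg19", tuple(layers), frozen_prefix=n_frozen)


ARCHITECTURES = {
    "basic_shallow": basic_shallow,
    "basic_deep": basic_deep,
    "vgg19": vgg19,
}


def get_architecture(name: str) -> ArchitectureSpec:
    try:
        return ARCHITECTURES[name]()
    except KeyError:
        raise ArchitectureError(
            f"unknown architecture {name!r}; choose from {sorted(ARCHITECTURES)}"
        ) from None


@dataclass(frozen=True)
class TrainingHyperparams:
    """Adam optimizer settings, batching and regularization.

    Per-architecture defaults follow the published training recipe:
    learning rate 5e-4 / 5e-5 / 5e-6, batch size 32 / 64 / 128 and
    200 / 200 / 50 epochs for basic_shallow / basic_deep / vgg19, with
    Adam's β₁ = 0.9 and β₂ = 0.999 throughout.
    """

    learning_rate: float = 5e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    epochs: int = 200
    dropout_rate: float = 0.5
    augmentation: bool = True
    seed: int = 0

    @classmethod
    def for_architecture(cls, name: str, **overrides) -> "TrainingHyperparams":
        defaults = {
            "basic_shallow": dict(learning_rate=5e-4, batch_size=32, epochs=200),
            "basic_deep": dict(learning_rate=5e-5, batch_size=64, epochs=200),
            "vgg19": dict(learning_rate=5e-6, batch_size=128, epochs=50),
        }
        if name not in defaults:
            raise ArchitectureError(f"unknown architecture {name!r}")
        kw = defaults[name] | overrides
        return cls(**kw)
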