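"""Declarative specifications of the two classifier architectures.

Both networks share a stem (32 7x7 convolutions, ReLU, 3x3 max pooling, both
stride 2) and a head (global average pooling, dropout 0.5, 2-way softmax):

* the residual network stacks four residual blocks with 64, 128, 256 and 512
  filters, each block two 3x3 convolutions (ReLU after each) plus a 1x1
  projection skip, downsampling x2 per stage;
* the inception network stacks nine 4-branch inception blocks with the filter
  table below, with an extra 3x3/stride-2 max pool after blocks 2 and 7.

A ``width_multiplier`` scales every filter count (floor 1) so that the same
topology can be trained at desk scale; conformance tests pin it to 1.0.
Specs serialize to plain dictionaries so that architecture conformance is
checkable without instantiating any parameters.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import ValidationError
from . import nn

#: per-block inception filter counts (f1, f2, f3, f4, f5, f6):
#: 1x1; 1x1 reduce before 3x3; 3x3; 1x1 reduce before 5x5; 5x5;
#: 1x1 projection after the 3x3-max-pool branch.
INCEPTION_FILTERS: tuple[tuple[int, ...], ...] = (
    (64, 96, 128, 16, 32, 32),
    (128, 128, 256, 32, 64, 64),
    (192, 96, 128, 16, 32, 32),
    (160, 112, 224, 24, 46, 64),
    (128, 128, 256, 24, 48, 64),
    (112, 144, 288, 32, 64, 64),
    (256, 160, 320, 32, 128, 128),
    (256, 160, 320, 32, 128, 128),
    (384, 192, 384, 48, 96, 64),
)

#: 3x3/stride-2 max pools sit after these (1-based) inception block indices.
INCEPTION_POOL_AFTER: tuple[int, ...] = (2, 7)

RESIDUAL_FILTERS: tuple[int, ...] = (64, 128, 256, 512)


@dataclass
class StemSpec:
    n_filters: int = 32
    kernel: int = 7
    stride: int = 2
    pool: int = 3
    pool_stride: int = 2
    activation: str = "relu"


@dataclass
class ResidualBlockSpec:
    n_filters: int
    kernel: int = 3
    stride: int = 2          # applied by the first body conv and the skip

    block_type: str = "residual"


@dataclass
class InceptionBlockSpec:
    filters: tuple[int, int, int, int, int, int]
    pool_after: bool = False  # 3x3/stride-2 max pool following this block

    block_type: str = "inception"


@dataclass
class ArchitectureSpec:
    name: str
    stem: StemSpec
    blocks: list
    dropout_rate: float = 0.5
    n_classes: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if not self.blocks:
            raise ValidationError("architecture needs at least one block")

    def to_dict(self) -> dict:
        return asdict(self)


def residual_spec() -> ArchitectureSpec:
    """The residual classifier: stem + 4 residual blocks (64..512) + head."""
    return ArchitectureSpec(
        name="osa-residual",
        stem=StemSpec(),
        blocks=[ResidualBlockSpec(n_filters=f) for f in RESIDUAL_FILTERS],
    )


def inception_spec() -> ArchitectureSpec:
    """The inception classifier: stem + 9 inception blocks + head."""
    return ArchitectureSpec(
        name="osa-inception",
        stem=StemSpec(),
        blocks=[
            InceptionBlockSpec(filters=f, pool_after=(i + 1) in INCEPTION_POOL_AFTER)
            for i, f in enumerate(INCEPTION_FILTERS)
        ],
    )


def _scaled(f: int, width_multiplier: float) -> int:
    return max(1, int(round(f * width_multiplier)))


@dataclass
class Classifier:
    """An instantiated network plus the spec and seed that produced it."""

    spec: ArchitectureSpec
    network: nn.Network
    seed: int
    width_multiplier: float = 1.0
    fitted: bool = False
    history: dict = field(default_factory=dict)

    def predict_proba(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        return self.network.predict_proba(
            np.asarray(images, dtype=np.float32), batch_size=batch_size)


def instantiate(spec: ArchitectureSpec, seed: int,
                width_multiplier: float = 1.0,
                dtype=np.float32) -> Classifier:
    """Build a classifier from a spec with seed-determined initialization."""
    if width_multiplier <= 0:
        raise ValidationError("width_multiplier must be positive")
    rng = np.random.default_rng(seed)
    wm = width_multiplier
    stem_filters = _scaled(spec.stem.n_filters, wm)
    layers: list[nn.Layer] = [
        nn.Affine(2.0, -1.0),   # center [0,1] pixels to [-1,1] for the stem
        nn.Conv2D(3, stem_filters, spec.stem.kernel, spec.stem.stride, rng,
                  dtype),
        nn.ReLU(),
        nn.MaxPool2D(spec.stem.pool, spec.stem.pool_stride),
    ]
    c = stem_filters
    for block in spec.blocks:
        if block.block_type == "residual":
            f = _scaled(block.n_filters, wm)
            layers.append(nn.ResidualBlock(c, f, rng, stride=block.stride,
                                           kernel=block.kernel, dtype=dtype))
            c = f
        elif block.block_type == "inception":
            filters = tuple(_scaled(f, wm) for f in block.filters)
            inc = nn.InceptionBlock(c, filters, rng, dtype=dtype)
            layers.append(inc)
            c = inc.c_out
            if block.pool_after:
                layers.append(nn.MaxPool2D(3, 2))
        else:
            raise ValidationError(f"unknown block type {block.block_type!r}")
    layers += [
        nn.GlobalAvgPool(),
        nn.Dropout(spec.dropout_rate, np.random.default_rng(seed + 1)),
        nn.Dense(c, spec.n_classes, rng, dtype),
    ]
    network = nn.Network(layers, input_shape=(224, 224, 3))
    return Classifier(spec=spec, network=network, seed=seed,
                      width_multiplier=width_multiplier)


def count_blocks(classifier: Classifier) -> dict:
    """Introspect the instantiated network against its generating spec.

    Walks the layer stack (not the spec) and reports block types, counts and
    per-block filter counts, plus pooling positions for the inception net.
    """
    blocks = []
    pool_after: list[int] = []
    n_seen = 0
    stem_filters = None
    dropout_rate = None
    for layer in classifier.network.stack.layers:
        if isinstance(layer, nn.Conv2D) and stem_filters is None:
            stem_filters = layer.c_out
        elif isinstance(layer, nn.ResidualBlock):
            n_seen += 1
            blocks.append({"type": "residual", "n_filters": layer.n_filters})
        elif isinstance(layer, nn.InceptionBlock):
            n_seen += 1
            blocks.append({"type": "inception", "filters": tuple(layer.filters)})
        elif isinstance(layer, nn.MaxPool2D) and n_seen > 0:
            pool_after.append(n_seen)
        elif isinstance(layer, nn.Dropout):
            dropout_rate = layer.rate
    return {
        "name": classifier.spec.name,
        "stem_filters": stem_filters,
        "n_blocks": len(blocks),
        "blocks": blocks,
        "pool_after_blocks": tuple(pool_after),
        "dropout_rate": dropout_rate,
        "n_parameters": classifier.network.n_parameters(),
    }
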