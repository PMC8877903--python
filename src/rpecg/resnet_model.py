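"""Residual CNN construction and architecture arithmetic.

The canonical ResNet family: a 7x7/64 stride-2 stem convolution, a 3x3
stride-2 max pool, four residual stages that halve the spatial size while
doubling the width, global average pooling and a softmax head.  Depths 18
and 34 use basic (two 3x3) blocks; 50/101/152 use bottleneck (1x1, 3x3,
1x1) blocks with 4x expansion.  For a 224x224 input the spatial schedule is
112, 56, 28, 14, 7, 1.

``base_width`` scales all stage widths down (used for the cheap stage-2
network in desk-scale experiments); ``input_size`` may differ from 224, the
schedule halves from whatever it is.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

__all__ = [
    "NetworkSpec",
    "conv_output_size",
    "build_network",
    "count_parameters",
    "forward_shapes",
    "ResNet",
]

_BLOCKS_PER_STAGE = {
    18: (2, 2, 2, 2),
    34: (3, 4, 6, 3),
    50: (3, 4, 6, 3),
    101: (3, 4, 23, 3),
    152: (3, 8, 36, 3),
}


@dataclass
class NetworkSpec:
    """Declarative description of a residual CNN."""

    depth: int = 18
    num_classes: int = 3
    input_size: int = 224
    base_width: int = 64          # width of the first stage's blocks
    shortcut: str = "projection"  # or "zero_pad"

    def __post_init__(self):
        if self.depth not in _BLOCKS_PER_STAGE:
            raise ValueError(
                f"unsupported depth {self.depth}; choose from {sorted(_BLOCKS_PER_STAGE)}"
            )
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.shortcut not in ("projection", "zero_pad"):
            raise ValueError("shortcut must be 'projection' or 'zero_pad'")

    @property
    def block_type(self) -> str:
        return "basic" if self.depth in (18, 34) else "bottleneck"

    @property
    def expansion(self) -> int:
        return 1 if self.block_type == "basic" else 4

    @property
    def blocks_per_stage(self) -> tuple:
        return _BLOCKS_PER_STAGE[self.depth]

    @property
    def stage_widths(self) -> tuple:
        # output channels per stage: (64,128,256,512) basic,
        # (256,512,1024,2048) bottleneck at base_width 64
        return tuple(self.base_width * (2 ** i) * self.expansion for i in range(4))

    def to_dict(self) -> dict:
        return asdict(self)


def conv_output_size(in_size: int, kernel: int, stride: int, padding: int) -> int:
    """Spatial output size of a convolution/pool: floor((n + 2p - k)/s) + 1."""
    if in_size <= 0 or kernel <= 0 or stride <= 0 or padding < 0:
        raise ValueError("in_size, kernel, stride must be positive; padding >= 0")
    out = (in_size + 2 * padding - kernel) // stride + 1
    if out < 1:
        raise ValueError(f"kernel {kernel} too large for input {in_size}")
    return out


def forward_shapes(spec: NetworkSpec) -> list[tuple[str, int, int]]:
    """(layer_name, spatial_size, channels) down the network.

    For a 224x224 input this reproduces the canonical output-size column:
    112 (stem conv), 56, 28, 14, 7 (stages), 1 (global average pool).
    """
    shapes = []
    s = conv_output_size(spec.input_size, 7, 2, 3)
    shapes.append(("conv1", s, 64 if spec.base_width == 64 else spec.base_width))
    s = conv_output_size(s, 3, 2, 1)  # max pool entering stage 1
    widths = spec.stage_widths
    for i in range(4):
        if i > 0:
            s = conv_output_size(s, 3, 2, 1)  # stride-2 first block of stages 2-4
        shapes.append((f"conv{i + 2}_x", s, widths[i]))
    shapes.append(("avgpool", 1, widths[-1]))
    return shapes


class ResNet(nn.Sequential):
    """A built residual network; ``spec`` records its architecture."""

    def __init__(self, layers: list, spec: NetworkSpec):
        super().__init__(layers)
        self.spec = spec

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities for a batch (inference mode)."""
        return nn.softmax(self.forward(x, train=False))


def build_network(depth: int = 18, num_classes: int = 3, input_size: int = 224,
                  base_width: int = 64, shortcut: str = "projection",
                  seed: int = 0, dtype=np.float32) -> ResNet:
    """Construct a residual CNN.

    Stem: 7x7/stride-2 convolution (padding 3), batch norm, ReLU, 3x3
    stride-2 max pool (padding 1).  Then four stages of residual blocks
    (counts per depth), stride-2 downsampling entering stages 2-4, global
    average pooling and a ``num_classes``-way fully connected head.  Batch
    normalization follows every convolution, before the activation.
    Shortcuts are 1x1 stride-matched projections where shapes change
    (``shortcut="zero_pad"`` selects subsampled zero-padded identities).
    """
    spec = NetworkSpec(depth=depth, num_classes=num_classes, input_size=input_size,
                       base_width=base_width, shortcut=shortcut)
    rng = np.random.default_rng(seed)
    block_cls = nn.BasicBlock if spec.block_type == "basic" else nn.Bottleneck
    w = spec.base_width

    layers: list = [
        nn.Conv2d(3, w, 7, stride=2, pad=3, rng=rng, dtype=dtype),
        nn.BatchNorm2d(w, dtype=dtype),
        nn.ReLU(),
        nn.MaxPool2d(3, stride=2, pad=1),
    ]
    in_ch = w
    for stage, n_blocks in enumerate(spec.blocks_per_stage):
        ch = w * (2 ** stage)
        for b in range(n_blocks):
            stride = 2 if (stage > 0 and b == 0) else 1
            layers.append(block_cls(in_ch, ch, stride=stride,
                                    shortcut=spec.shortcut, rng=rng, dtype=dtype))
            in_ch = ch * block_cls.expansion
    layers += [
        nn.GlobalAvgPool(),
        nn.Linear(in_ch, num_classes, rng=rng, dtype=dtype),
    ]
    return ResNet(layers, spec)


def count_parameters(network: nn.Layer) -> int:
    """Total trainable scalars: conv + fc weights/biases, BN scale/shift."""
    return int(sum(p.size for p in network.params()))
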