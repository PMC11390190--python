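"""CNN15 and CNN4 architectures and shape-arithmetic conformance checks.

CNN15 is the segmentation network: a 353x353 two-channel input (the
preprocessed image paired with its soft-morphology-enhanced companion)
passes through 15 convolutional layers and 2 max-pooling layers, a
sub-pixel "double size" rearrangement (22x22x256 -> 44x44x64) and a
final single-filter convolution, giving a 44x44 per-cell nodule
probability map (one map cell per 8x8 input block) through a logistic
squashing.

CNN4 is the patch classifier: a 64x64 two-channel patch through 4
conv / 4 max-pool layers down to a 1x1x384 descriptor, then two fully
connected layers and a softmax over the two class labels
(nodule / not-nodule).

PReLU follows every convolution; local response normalization sits
after the first two activation sites of each network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from thyronet import nn


def conv_output_size(in_side: int, filter_side: int, padding: int, stride: int) -> int:
    """Spatial output side of a convolution or pooling window.

    ``floor((in + 2*padding - filter) / stride) + 1``.
    """
    if in_side < 0 or filter_side < 0 or padding < 0:
        raise ValueError("sizes must be nonnegative")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if in_side + 2 * padding < filter_side:
        raise ValueError("filter larger than padded input")
    return (in_side + 2 * padding - filter_side) // stride + 1


@dataclass(frozen=True)
class LayerSpec:
    """One row of an architecture table."""

    name: str
    kind: str                    # conv | maxpool | double_size | fully_connected
    in_side: int
    in_channels: int
    filter_side: int | None
    out_channels: int
    padding: int | None
    stride: int | None
    out_side: int

    def computed_out_side(self) -> int:
        if self.kind in ("conv", "maxpool"):
            return conv_output_size(self.in_side, self.filter_side,
                                    self.padding, self.stride)
        if self.kind == "double_size":
            return self.in_side * 2
        return 1  # fully connected collapses spatial extent


@dataclass(frozen=True)
class NormParams:
    """Cross-channel LRN parameters (k, n, alpha, beta)."""

    k: float
    n: int
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("window n must be >= 1")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass(frozen=True)
class ArchitectureSpec:
    name: str
    layers: tuple[LayerSpec, ...]
    norm_sites: tuple[int, ...]          # indices into layers carrying LRN
    norm_params: tuple[NormParams, ...]

    def conv_count(self) -> int:
        return sum(1 for l in self.layers if l.kind == "conv")

    def pool_count(self) -> int:
        return sum(1 for l in self.layers if l.kind == "maxpool")

    def fc_count(self) -> int:
        return sum(1 for l in self.layers if l.kind == "fully_connected")


def _rows(table: list[tuple]) -> tuple[LayerSpec, ...]:
    return tuple(LayerSpec(*row) for row in table)


# name, kind, in_side, in_ch, filter, out_ch, pad, stride, out_side
_CNN15_TABLE = [
    ("Conv1",        "conv",        353, 2,   13, 96,  6, 2, 177),
    ("Max-pooling1", "maxpool",     177, 96,  3,  96,  1, 2, 89),
    ("Conv2a",       "conv",        89,  96,  5,  256, 2, 2, 45),
    ("Conv2b",       "conv",        45,  256, 5,  256, 2, 1, 45),
    ("Max-pooling2", "maxpool",     45,  256, 3,  256, 0, 2, 22),
    ("Conv3",        "conv",        22,  256, 3,  384, 1, 1, 22),
    ("Conv4",        "conv",        22,  384, 3,  384, 1, 1, 22),
    ("Conv5a",       "conv",        22,  384, 3,  384, 1, 1, 22),
    ("Conv5b",       "conv",        22,  384, 3,  384, 1, 1, 22),
    ("Conv5c",       "conv",        22,  384, 3,  384, 1, 1, 22),
    ("Conv5d",       "conv",        22,  384, 3,  384, 1, 1, 22),
    ("Conv5e",       "conv",        22,  384, 3,  384, 1, 1, 22),
    ("Conv5f",       "conv",        22,  384, 3,  384, 1, 1, 22),
    ("Conv5g",       "conv",        22,  384, 3,  384, 1, 1, 22),
    ("Conv5h",       "conv",        22,  384, 3,  384, 1, 1, 22),
    ("Conv5i",       "conv",        22,  384, 3,  256, 1, 1, 22),
    ("DS",           "double_size", 22,  256, None, 64, None, None, 44),
    ("Conv6",        "conv",        44,  64,  3,  1,   1, 1, 44),
]

_CNN4_TABLE = [
    ("Conv1",        "conv",            64, 2,  5, 64,  2, 1, 64),
    ("Max-pooling1", "maxpool",         64, 64, 3, 64,  1, 2, 32),
    ("Conv2",        "conv",            32, 64, 5, 64,  2, 1, 32),
    ("Max-pooling2", "maxpool",         32, 64, 3, 64,  1, 2, 16),
    ("Conv3",        "conv",            16, 64, 3, 64,  1, 1, 16),
    ("Max-pooling3", "maxpool",         16, 64, 2, 64,  0, 2, 8),
    ("Conv4",        "conv",            8,  64, 3, 384, 1, 1, 8),
    ("Max-pooling4", "maxpool",         8, 384, 8, 384, 0, 8, 1),
    ("Fc1",          "fully_connected", 1, 384, None, 192, None, None, 1),
    ("Fc2",          "fully_connected", 1, 192, None, 2,   None, None, 1),
]

CNN15_NORM_PARAMS = (NormParams(96, 24, 0.0005, 0.75),
                     NormParams(256, 16, 0.0005, 0.75))
CNN4_NORM_PARAMS = (NormParams(64, 24, 0.0005, 0.75),
                    NormParams(64, 16, 0.0005, 0.75))


def cnn15_spec() -> ArchitectureSpec:
    """The canonical CNN15 layer table: 15 conv + 2 max-pool layers,
    LRN after Conv1 and Conv2a."""
    return ArchitectureSpec(name="CNN15", layers=_rows(_CNN15_TABLE),
                            norm_sites=(0, 2), norm_params=CNN15_NORM_PARAMS)


def cnn4_spec(n_logits: int = 2) -> ArchitectureSpec:
    """The canonical CNN4 layer table: 4 conv + 4 max-pool + 2 fully
    connected layers, LRN after Conv1 and Conv2.

    The printed table ends in a single output unit while the text
    describes a softmax over 2 class labels; the 2-logit head is the
    default, ``n_logits=1`` gives the single-logit variant.
    """
    table = list(_CNN4_TABLE)
    if n_logits == 1:
        name, kind, i, ic, f, _, p, s, o = table[-1]
        table[-1] = (name, kind, i, ic, f, 1, p, s, o)
    elif n_logits != 2:
        raise ValueError("n_logits must be 1 or 2")
    return ArchitectureSpec(name="CNN4", layers=_rows(table),
                            norm_sites=(0, 2), norm_params=CNN4_NORM_PARAMS)


@dataclass
class ConformanceReport:
    """Result of re-deriving an architecture's shape chain."""

    name: str
    mismatches: list[str] = field(default_factory=list)
    conv_layers: int = 0
    pool_layers: int = 0
    fc_layers: int = 0
    final_shape: tuple[int, int, int] = (0, 0, 0)  # (side, side, channels)

    @property
    def conformant(self) -> bool:
        return not self.mismatches


def validate_architecture(spec: ArchitectureSpec,
                          reference: ArchitectureSpec | None = None) -> ConformanceReport:
    """Recompute every output side/channel count and compare against the
    canonical printed table.

    Shape chaining (layer j's output feeding layer j+1) is also checked;
    an empty mismatch list means the spec is conformant.
    """
    if not spec.layers:
        raise ValueError("spec has no layers")
    if reference is None:
        reference = cnn15_spec() if spec.name == "CNN15" else cnn4_spec()
    report = ConformanceReport(name=spec.name)
    prev: LayerSpec | None = None
    for layer, ref in zip(spec.layers, reference.layers):
        computed = layer.computed_out_side()
        if computed != ref.out_side:
            report.mismatches.append(
                f"{layer.name}: computed out_side {computed} != table {ref.out_side}")
        if layer.out_channels != ref.out_channels:
            report.mismatches.append(
                f"{layer.name}: out_channels {layer.out_channels} != table {ref.out_channels}")
        if prev is not None and (layer.in_side != prev.out_side
                                 or layer.in_channels != prev.out_channels):
            report.mismatches.append(
                f"{layer.name}: input ({layer.in_side},{layer.in_channels}) does not "
                f"chain from ({prev.out_side},{prev.out_channels})")
        prev = layer
    if len(spec.layers) != len(reference.layers):
        report.mismatches.append(
            f"layer count {len(spec.layers)} != table {len(reference.layers)}")
    report.conv_layers = spec.conv_count()
    report.pool_layers = spec.pool_count()
    report.fc_layers = spec.fc_count()
    last = spec.layers[-1]
    report.final_shape = (last.out_side, last.out_side, last.out_channels)
    return report


class Network(nn.Sequential):
    """A layer stack plus its table spec and output head."""

    def __init__(self, layers, spec: ArchitectureSpec, head: str):
        super().__init__(layers)
        self.spec = spec
        self.head = head  # "sigmoid" (per-cell map) or "softmax" (class dist.)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Forward pass through the head; input (N, C, H, W) float32."""
        logits = self.forward(np.asarray(x, dtype=np.float32))
        if self.head == "sigmoid":
            return nn.sigmoid(logits)
        return nn.softmax(logits)

    def save_weights(self, path) -> None:
        """Checkpoint all parameters to an .npz archive."""
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params())}
        np.savez(path, **arrays)

    def load_weights(self, path) -> None:
        with np.load(path) as ckpt:
            params = self.params()
            if len(ckpt.files) != len(params):
                raise ValueError("checkpoint does not match this architecture")
            for i, p in enumerate(params):
                data = ckpt[f"p{i}"]
                if data.shape != p.data.shape:
                    raise ValueError(f"parameter {i}: shape {data.shape} "
                                     f"!= expected {p.data.shape}")
                p.data[...] = data


def _conv_block(row: LayerSpec, slope: float) -> list[nn.Layer]:
    return [nn.Conv2d(row.in_channels, row.out_channels, row.filter_side,
                      stride=row.stride, padding=row.padding),
            nn.PReLU(slope)]


def build_cnn15(prelu_slope: float = 0.9) -> Network:
    """Assemble CNN15 per its table: PReLU after every convolution, LRN
    after the first two activation sites, sub-pixel DS before the final
    single-map convolution; the head is a per-cell logistic squashing so
    a 2x353x353 input yields a 44x44 probability map."""
    spec = cnn15_spec()
    rows = {r.name: r for r in spec.layers}
    layers: list[nn.Layer] = []
    layers += _conv_block(rows["Conv1"], prelu_slope)
    layers.append(nn.LocalResponseNorm(*_np_tuple(CNN15_NORM_PARAMS[0])))
    layers.append(nn.MaxPool2d(3, stride=2, padding=1))
    layers += _conv_block(rows["Conv2a"], prelu_slope)
    layers.append(nn.LocalResponseNorm(*_np_tuple(CNN15_NORM_PARAMS[1])))
    layers += _conv_block(rows["Conv2b"], prelu_slope)
    layers.append(nn.MaxPool2d(3, stride=2, padding=0))
    for name in ("Conv3", "Conv4", "Conv5a", "Conv5b", "Conv5c", "Conv5d",
                 "Conv5e", "Conv5f", "Conv5g", "Conv5h", "Conv5i"):
        layers += _conv_block(rows[name], prelu_slope)
    layers.append(nn.PixelShuffle(2))
    layers.append(nn.Conv2d(64, 1, 3, stride=1, padding=1))
    return Network(layers, spec, head="sigmoid")


def build_cnn4(prelu_slope: float = 0.9, n_logits: int = 2) -> Network:
    """Assemble CNN4 per its table, ending in Fc1 (384->192) and the
    class head (192->2 logits by default; 1-logit variant available)."""
    spec = cnn4_spec(n_logits=n_logits)
    rows = {r.name: r for r in spec.layers}
    layers: list[nn.Layer] = [
        *_conv_block(rows["Conv1"], prelu_slope),
        nn.LocalResponseNorm(*_np_tuple(CNN4_NORM_PARAMS[0])),
        nn.MaxPool2d(3, stride=2, padding=1),
        *_conv_block(rows["Conv2"], prelu_slope),
        nn.LocalResponseNorm(*_np_tuple(CNN4_NORM_PARAMS[1])),
        nn.MaxPool2d(3, stride=2, padding=1),
        *_conv_block(rows["Conv3"], prelu_slope),
        nn.MaxPool2d(2, stride=2, padding=0),
        *_conv_block(rows["Conv4"], prelu_slope),
        nn.MaxPool2d(8, stride=8, padding=0),
        nn.Flatten(),
        nn.Linear(384, 192),
        nn.PReLU(prelu_slope),
        nn.Linear(192, n_logits),
    ]
    head = "softmax" if n_logits == 2 else "sigmoid"
    return Network(layers, spec, head=head)


def _np_tuple(p: NormParams) -> tuple[float, int, float, float]:
    return (p.k, p.n, p.alpha, p.beta)
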