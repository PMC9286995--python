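"""Improved residual U-Net for left-ventricle segmentation.

The network is a U-shaped encoder/decoder built from residual units and
three families of skip connections:

* **short** skips live inside each residual unit: an additive identity
  path from the unit input to its output (through a 1x1 projection when
  channel counts differ) plus a concatenative path that re-injects the
  unit input into the second convolution block;
* **medium** skips feed the raw model input into every encoder step: at
  step ``i`` the input passes through a per-level 1x1 convolution with
  stride ``2**i`` and is concatenated with the downsampled feature map;
* **long** skips are the classic U-Net concatenations from each encoder
  level to the matching decoder level.

Convolution blocks come in two flavours.  ``standard`` is a plain 3x3
convolution.  ``depthwise_separable`` builds half the output channels
with a 3x3 convolution (S1) and the other half by a per-channel 3x3
convolution of S1 (S2), concatenated — a ghost-style block with
9*c1*c2/2 + 9*c2/2 kernel weights instead of 9*c1*c2.

The head is a 1x1 convolution to ``n_classes`` followed by a per-pixel
softmax, so the output has the spatial resolution of the input.
Endocardium and epicardium are segmented by two separately trained
binary networks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml
from skimage.measure import label as cc_label

from .nn import autograd as ag
from .nn.autograd import Tensor, no_grad
from .nn.layers import (
    DTYPE,
    BatchNorm2d,
    Conv1x1,
    Conv3x3,
    ConvTranspose2x2,
    DepthwiseConv3x3,
    MaxPool2x2,
    Module,
)

CONV_TYPES = ("standard", "depthwise_separable")
DOWNSAMPLE_TYPES = ("pooling", "strided")


@dataclass
class ArchConfig:
    """Declarative description of one network variant.

    Setting ``use_medium_skip=False``, ``use_short_skip=False`` and
    ``conv_type="standard"`` yields a plain residual U-Net baseline;
    turning the flags back on reproduces the ablation ladder
    (baseline -> +skip connections -> +separable convolutions).
    """

    input_size: int = 128
    in_channels: int = 1
    n_classes: int = 2
    n_levels: int = 4
    base_channels: int = 32
    use_medium_skip: bool = True
    use_short_skip: bool = True
    conv_type: str = "depthwise_separable"
    downsample: str = "pooling"
    seed: int = 0

    def __post_init__(self):
        if self.conv_type not in CONV_TYPES:
            raise ValueError(f"conv_type must be one of {CONV_TYPES}, got {self.conv_type!r}")
        if self.downsample not in DOWNSAMPLE_TYPES:
            raise ValueError(f"downsample must be one of {DOWNSAMPLE_TYPES}")
        if self.input_size % (2**self.n_levels) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^n_levels={2**self.n_levels}"
            )
        if self.conv_type == "depthwise_separable" and self.base_channels % 2 != 0:
            raise ValueError("depthwise_separable conv requires even channel counts")
        if min(self.n_levels, self.base_channels, self.in_channels, self.n_classes) < 1:
            raise ValueError("all architecture sizes must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchConfig":
        return cls(**d)


class StandardConvBlock(Module):
    """3x3 convolution producing pre-normalization features."""

    def __init__(self, c_in: int, c_out: int, rng):
        super().__init__()
        self.conv = Conv3x3(c_in, c_out, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv.forward(x)


class DepthwiseSeparableBlock(Module):
    """Ghost-style block: S1 = 3x3 conv (c_out/2), S2 = depthwise 3x3 of S1.

    Returns the pre-normalization concatenation [S1, S2]; callers append
    BN + ReLU (possibly after a residual join).
    """

    def __init__(self, c_in: int, c_out: int, rng):
        super().__init__()
        if c_out % 2 != 0:
            raise ValueError(
                f"depthwise-separable block needs an even output channel count, got {c_out}"
            )
        self.half = c_out // 2
        self.primary = Conv3x3(c_in, self.half, rng)
        self.cheap = DepthwiseConv3x3(self.half, rng)

    def forward(self, x: Tensor) -> Tensor:
        return ag.dsconv3x3(x, self.primary.weight, self.cheap.weight)


def _conv_block(c_in: int, c_out: int, conv_type: str, rng) -> Module:
    if conv_type == "standard":
        return StandardConvBlock(c_in, c_out, rng)
    return DepthwiseSeparableBlock(c_in, c_out, rng)


class DSConvBNReLU(Module):
    """Stand-alone depthwise-separable convolution block with BN + ReLU."""

    def __init__(self, c_in: int, c_out: int, rng=None, seed: int = 0):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(seed)
        self.block = DepthwiseSeparableBlock(c_in, c_out, rng)
        self.bn = BatchNorm2d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(self.bn.forward(self.block.forward(x)))


def dsconv_block(c_in: int, c_out: int, seed: int = 0) -> DSConvBNReLU:
    """Build a depthwise-separable convolution block mapping c_in -> c_out channels."""
    return DSConvBNReLU(c_in, c_out, seed=seed)


class ResidualUnit(Module):
    """Two convolution blocks with the two short skip connections.

    Wiring (``use_short_skip=True``)::

        f1 = ReLU(BN(conv1(x)))
        y  = conv2(concat[f1, x])          # concatenative short skip
        y  = y + proj(x)                   # additive short skip
        out = ReLU(BN(y))

    ``proj`` is the identity when channel counts match, else a 1x1
    convolution.  With ``use_short_skip=False`` the unit degrades to a
    plain pair of conv+BN+ReLU blocks (the ablation baseline).
    Spatial size is preserved throughout.
    """

    def __init__(self, c_in: int, c_out: int, conv_type: str, use_short_skip: bool, rng):
        super().__init__()
        self.use_short_skip = use_short_skip
        self.block1 = _conv_block(c_in, c_out, conv_type, rng)
        self.bn1 = BatchNorm2d(c_out)
        c2_in = c_out + c_in if use_short_skip else c_out
        self.block2 = _conv_block(c2_in, c_out, conv_type, rng)
        self.bn2 = BatchNorm2d(c_out)
        self.proj = None
        if use_short_skip and c_in != c_out:
            self.proj = Conv1x1(c_in, c_out, rng)

    def forward(self, x: Tensor) -> Tensor:
        f1 = ag.relu(self.bn1.forward(self.block1.forward(x)))
        if self.use_short_skip:
            y = self.block2.forward(ag.concat([f1, x], axis=1))
            identity = self.proj.forward(x) if self.proj is not None else x
            y = ag.add(y, identity)
        else:
            y = self.block2.forward(f1)
        return ag.relu(self.bn2.forward(y))


class ImprovedResUNet(Module):
    """The full encoder/decoder network described by an :class:`ArchConfig`."""

    def __init__(self, config: ArchConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.base_channels
        ct = config.conv_type
        ss = config.use_short_skip

        self.enc_units: list[ResidualUnit] = []
        self.pools: list[Module] = []
        self.medium_convs: list[Conv1x1 | None] = []
        enc_out: list[int] = []

        c_in = config.in_channels
        for level in range(config.n_levels):
            c_out = c * (2**level)
            self.enc_units.append(ResidualUnit(c_in, c_out, ct, ss, rng))
            enc_out.append(c_out)
            if config.downsample == "pooling":
                self.pools.append(MaxPool2x2())
            else:
                self.pools.append(Conv1x1(c_out, c_out, rng, stride=2))
            c_in = c_out
            if config.use_medium_skip:
                med = Conv1x1(config.in_channels, config.base_channels, rng,
                              stride=2 ** (level + 1))
                self.medium_convs.append(med)
                c_in = c_out + config.base_channels
            else:
                self.medium_convs.append(None)

        c_bottom = c * (2**config.n_levels)
        self.transition = ResidualUnit(c_in, c_bottom, ct, ss, rng)

        self.up_convs: list[ConvTranspose2x2] = []
        self.dec_units: list[ResidualUnit] = []
        c_prev = c_bottom
        for level in reversed(range(config.n_levels)):
            c_skip = enc_out[level]
            self.up_convs.append(ConvTranspose2x2(c_prev, c_skip, rng))
            self.dec_units.append(ResidualUnit(2 * c_skip, c_skip, ct, ss, rng))
            c_prev = c_skip

        self.head = Conv1x1(c_prev, config.n_classes, rng, bias=True)

    def forward(self, x: Tensor) -> Tensor:
        """Logits of shape (N, n_classes, H, W) for input (N, in_channels, H, W)."""
        skips: list[Tensor] = []
        h = x
        for level in range(self.config.n_levels):
            h = self.enc_units[level].forward(h)
            skips.append(h)
            h = self.pools[level].forward(h)
            med = self.medium_convs[level]
            if med is not None:
                h = ag.concat([h, med.forward(x)], axis=1)
        h = self.transition.forward(h)
        for i, level in enumerate(reversed(range(self.config.n_levels))):
            h = self.up_convs[i].forward(h)
            h = ag.concat([h, skips[level]], axis=1)
            h = self.dec_units[i].forward(h)
        return self.head.forward(h)

    def forward_probs(self, x: Tensor) -> Tensor:
        return ag.softmax(self.forward(x), axis=1)


def build_model(config: ArchConfig) -> ImprovedResUNet:
    """Construct a network from its declarative configuration (seeded init)."""
    return ImprovedResUNet(config)


def param_count(model: Module) -> int:
    """Exact number of trainable scalar weights in the network."""
    return model.param_count()


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Per-image z-score normalization applied before the network."""
    image = np.asarray(image, dtype=np.float64)
    sd = image.std()
    if sd == 0:
        return np.zeros_like(image, dtype=DTYPE)
    return ((image - image.mean()) / sd).astype(DTYPE)


def predict(model: ImprovedResUNet, image: np.ndarray,
            keep_largest_component: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Segment one image.

    Returns ``(prob_map, mask)`` where ``prob_map`` has shape
    (H, W, n_classes) with per-pixel class probabilities and ``mask`` is
    the boolean foreground segmentation.  The mask is the argmax class
    (ties resolve to background, the lowest class index); optionally only
    the largest 4-connected foreground component is kept, since the LV
    is a single structure.
    """
    cfg = model.config
    image = np.asarray(image)
    if image.shape != (cfg.input_size, cfg.input_size):
        raise ValueError(
            f"image shape {image.shape} does not match model input "
            f"({cfg.input_size}, {cfg.input_size})"
        )
    model.eval()
    x = normalize_image(image)[None, None]
    with no_grad():
        probs = model.forward_probs(Tensor(x)).data[0]
    prob_map = np.moveaxis(probs, 0, -1)
    mask = prob_map.argmax(axis=-1) == 1
    if keep_largest_component and mask.any():
        lab = cc_label(mask, connectivity=1)
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        mask = lab == counts.argmax()
    return prob_map, mask


# ---------------------------------------------------------------------------
# checkpoints: weights as .npz with the ArchConfig serialized alongside


def save_checkpoint(model: ImprovedResUNet, path) -> None:
    """Write weights (.npz) plus a self-describing .yaml config next to it."""
    path = str(path)
    arrays = {f"param::{k}": v.data for k, v in model.named_parameters().items()}
    arrays.update({f"buffer::{k}": v for k, v in model.buffers().items()})
    np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
    cfg_path = (path[:-4] if path.endswith(".npz") else path) + ".yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(model.config.to_dict(), fh)


def load_checkpoint(path) -> ImprovedResUNet:
    path = str(path)
    if not path.endswith(".npz"):
        path = path + ".npz"
    cfg_path = path[:-4] + ".yaml"
    with open(cfg_path) as fh:
        config = ArchConfig.from_dict(yaml.safe_load(fh))
    model = build_model(config)
    data = np.load(path)
    params = model.named_parameters()
    buffers = model.buffers()
    for key in data.files:
        kind, name = key.split("::", 1)
        if kind == "param":
            params[name].data = data[key].astype(params[name].data.dtype)
        else:
            buffers[name][...] = data[key]
    return model
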