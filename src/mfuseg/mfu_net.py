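"""The multiple-filter U-net (MFU-net).

The building block is the MF block: three parallel convolutions with
kernel sizes 1x1, 3x3 and 5x5 (same-size padding 0/1/2, stride 1) whose
outputs are concatenated along channels and rectified.  Small kernels pick
up local detail, the 5x5 kernel wider context; concatenation lets the
decoder use both at once, in the spirit of Inception-style multi-scale
blocks.

The network is U-shaped: a ResNet18-style encoder (7x7 stem stride 2,
3x3 max-pool stride 2, four stages of two basic residual blocks, channel
widths w, 2w, 4w, 8w) and a decoder of exactly ten MF blocks arranged as
five upsampling levels of two blocks each.  Each level doubles resolution
with nearest-neighbour upsampling, optionally concatenates the matching
encoder feature map (skip wiring ``"unet"``: one skip per encoder stage;
``"single"``: only the highest-resolution stem skip), and applies its two
MF blocks.  A 1x1 convolution maps the final features to the three class
scores (background, liver, tumor).

A slice prediction is the per-pixel softmax over the three scores; the
label map takes the class of highest probability, and per-class binary
masks at probability >= 0.5 are available separately.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import ops
from .volume_io import CTVolume, LabelVolume, reconstruct_volume

DOWNSAMPLING_FACTOR = 32


def split_branch_channels(width: int) -> tuple[int, int, int]:
    """Split a block width across the (1x1, 3x3, 5x5) branches as evenly as
    possible, remainder to the 3x3 branch."""
    if width < 3:
        raise ValueError(f"MF block width must be >= 3 to populate all branches, got {width}")
    c = width // 3
    return (c, width - 2 * c, c)


@dataclass(frozen=True)
class MFBlockSpec:
    """Architecture of one MF block: input channels and per-branch widths."""

    in_channels: int
    branch_channels: tuple[int, int, int]

    def __post_init__(self):
        if self.in_channels < 1 or any(c < 1 for c in self.branch_channels):
            raise ValueError(f"channel counts must be positive: {self}")

    @property
    def out_channels(self) -> int:
        return sum(self.branch_channels)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description of the full MFU-net.

    ``base_width`` scales every stage; 64 is the full-size network, small
    values give desk-scale variants for CPU training.  ``skips`` selects the
    skip wiring: ``"unet"`` (one per encoder stage) or ``"single"`` (only
    the highest-resolution stem skip).
    """

    in_channels: int = 1
    num_classes: int = 3
    base_width: int = 64
    skips: str = "unet"
    batch_norm: bool = True

    def __post_init__(self):
        if self.num_classes != 3:
            raise ValueError("the segmentation head is three-class (background, liver, tumor)")
        if self.base_width < 3:
            raise ValueError("base_width must be >= 3")
        if self.skips not in ("unet", "single"):
            raise ValueError(f"skips must be 'unet' or 'single', got {self.skips!r}")

    @property
    def encoder_widths(self) -> tuple[int, int, int, int]:
        b = self.base_width
        return (b, 2 * b, 4 * b, 8 * b)

    @property
    def decoder_widths(self) -> tuple[int, int, int, int, int]:
        b = self.base_width
        return (4 * b, 2 * b, b, b, b)

    @property
    def skip_channels(self) -> tuple[int, int, int, int, int]:
        """Encoder channels concatenated at each decoder level (0 = no skip)."""
        b = self.base_width
        if self.skips == "unet":
            return (4 * b, 2 * b, b, b, 0)   # stage3, stage2, stage1, stem, none
        return (0, 0, 0, b, 0)               # stem skip only

    def mf_block_specs(self) -> list[MFBlockSpec]:
        """The ten decoder MF blocks, in forward order."""
        specs = []
        in_ch = self.encoder_widths[-1]  # bottleneck
        for level, (w, sk) in enumerate(zip(self.decoder_widths, self.skip_channels)):
            first_in = in_ch + sk
            specs.append(MFBlockSpec(first_in, split_branch_channels(w)))
            specs.append(MFBlockSpec(w, split_branch_channels(w)))
            in_ch = w
        assert len(specs) == 10
        return specs

    def to_json(self) -> str:
        return json.dumps({
            "in_channels": self.in_channels, "num_classes": self.num_classes,
            "base_width": self.base_width, "skips": self.skips,
            "batch_norm": self.batch_norm,
        }, sort_keys=True)

    def spec_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


class MFBlock(nn.Module):
    """Parallel 1x1 / 3x3 / 5x5 convolutions, concatenated, rectified."""

    # the 5x5 branch pads by 2 on each side, so anything smaller than 2x2
    # would be convolved against padding alone
    MIN_SPATIAL = 2

    def __init__(self, spec: MFBlockSpec, rng: np.random.Generator, batch_norm: bool = True):
        super().__init__()
        self.spec = spec
        c1, c3, c5 = spec.branch_channels
        self.conv1 = nn.Conv2d(spec.in_channels, c1, 1, rng, padding=0)
        self.conv3 = nn.Conv2d(spec.in_channels, c3, 3, rng, padding=1)
        self.conv5 = nn.Conv2d(spec.in_channels, c5, 5, rng, padding=2)
        self.use_bn = batch_norm
        if batch_norm:
            self.bn1 = nn.BatchNorm2d(c1)
            self.bn3 = nn.BatchNorm2d(c3)
            self.bn5 = nn.BatchNorm2d(c5)

    def forward(self, x: nn.Var) -> nn.Var:
        n, c, h, w = x.data.shape
        if c != self.spec.in_channels:
            raise ValueError(f"MF block expects {self.spec.in_channels} input channels, got {c}")
        if h < self.MIN_SPATIAL or w < self.MIN_SPATIAL:
            raise ValueError(
                f"MF block input {h}x{w} too small for the 5x5 kernel after the "
                f"padding contract (needs >= {self.MIN_SPATIAL}x{self.MIN_SPATIAL})"
            )
        b1, b3, b5 = self.conv1(x), self.conv3(x), self.conv5(x)
        if self.use_bn:
            b1, b3, b5 = self.bn1(b1), self.bn3(b3), self.bn5(b5)
        return ops.relu(ops.concat([b1, b3, b5], axis=1))


def mf_block_forward(block: MFBlock, x: np.ndarray) -> np.ndarray:
    """Convenience: run an MF block on a raw NCHW array, returning an array."""
    with nn.no_grad():
        return block(nn.Var(np.asarray(x, dtype=float))).data


class BasicBlock(nn.Module):
    """ResNet basic residual block: two 3x3 convolutions plus shortcut."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng, stride=stride, padding=1, bias=False)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng, stride=1, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.downsample = stride != 1 or in_ch != out_ch
        if self.downsample:
            self.proj = nn.Conv2d(in_ch, out_ch, 1, rng, stride=stride, bias=False)
            self.proj_bn = nn.BatchNorm2d(out_ch)

    def forward(self, x: nn.Var) -> nn.Var:
        y = ops.relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        sc = self.proj_bn(self.proj(x)) if self.downsample else x
        return ops.relu(ops.add(y, sc))


class ResNet18Encoder(nn.Module):
    """7x7 stem + max-pool + four stages of two basic blocks each."""

    def __init__(self, in_channels: int, base_width: int, rng: np.random.Generator):
        super().__init__()
        b = base_width
        self.stem = nn.Conv2d(in_channels, b, 7, rng, stride=2, padding=3, bias=False)
        self.stem_bn = nn.BatchNorm2d(b)
        widths = (b, 2 * b, 4 * b, 8 * b)
        stages = []
        in_ch = b
        for i, w in enumerate(widths):
            stride = 1 if i == 0 else 2
            stages.append(nn.ModuleList([
                BasicBlock(in_ch, w, stride, rng),
                BasicBlock(w, w, 1, rng),
            ]))
            in_ch = w
        self.stages = nn.ModuleList(stages)

    def forward(self, x: nn.Var) -> list[nn.Var]:
        """Returns [stem (1/2), stage1 (1/4), stage2 (1/8), stage3 (1/16),
        stage4 (1/32)] feature maps."""
        f0 = ops.relu(self.stem_bn(self.stem(x)))
        y = ops.max_pool2d(f0, kernel=3, stride=2, padding=1)
        feats = [f0]
        for stage in self.stages:
            for block in stage:
                y = block(y)
            feats.append(y)
        return feats


class DecoderLevel(nn.Module):
    """2x nearest-neighbour upsample -> optional skip concat -> two MF blocks."""

    def __init__(self, spec_first: MFBlockSpec, spec_second: MFBlockSpec,
                 rng: np.random.Generator, batch_norm: bool):
        super().__init__()
        self.mf1 = MFBlock(spec_first, rng, batch_norm)
        self.mf2 = MFBlock(spec_second, rng, batch_norm)

    def forward(self, x: nn.Var, skip: nn.Var | None) -> nn.Var:
        y = ops.upsample_nearest2(x)
        if skip is not None:
            if skip.data.shape[2:] != y.data.shape[2:]:
                raise ValueError(
                    f"skip connection shape mismatch at merge: decoder {y.data.shape} "
                    f"vs encoder {skip.data.shape}"
                )
            y = ops.concat([y, skip], axis=1)
        return self.mf2(self.mf1(y))


class MFUNet(nn.Module):
    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.encoder = ResNet18Encoder(spec.in_channels, spec.base_width, rng)
        block_specs = spec.mf_block_specs()
        levels = []
        for lvl in range(5):
            levels.append(DecoderLevel(block_specs[2 * lvl], block_specs[2 * lvl + 1],
                                       rng, spec.batch_norm))
        self.levels = nn.ModuleList(levels)
        self.head = nn.Conv2d(spec.decoder_widths[-1], spec.num_classes, 1, rng)

    def forward(self, x: nn.Var) -> nn.Var:
        n, c, h, w = x.data.shape
        if c != self.spec.in_channels:
            raise ValueError(f"expected {self.spec.in_channels} input channel(s), got {c}")
        if h % DOWNSAMPLING_FACTOR or w % DOWNSAMPLING_FACTOR:
            raise ValueError(
                f"input spatial dims must be divisible by {DOWNSAMPLING_FACTOR}, got {h}x{w}"
            )
        feats = self.encoder(x)  # [stem, s1, s2, s3, s4]
        if self.spec.skips == "unet":
            skip_order = [feats[3], feats[2], feats[1], feats[0], None]
        else:
            skip_order = [None, None, None, feats[0], None]
        y = feats[4]
        for level, skip in zip(self.levels, skip_order):
            y = level(y, skip)
        return self.head(y)


def build_mfunet(spec: NetworkSpec, seed: int) -> MFUNet:
    """Build an MFU-net with deterministic seeded initialisation."""
    rng = np.random.default_rng(seed)
    return MFUNet(spec, rng)


def parameter_count(net: nn.Module) -> int:
    return int(sum(p.data.size for p in net.parameters()))


def predict_slice(net: MFUNet, plane: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict one preprocessed slice.

    Returns (prob_maps, labels): per-pixel softmax probabilities (3, H, W)
    and the argmax label map (H, W) over {0, 1, 2}.
    """
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise ValueError(f"expected a 2-D slice, got {plane.ndim}-D")
    net.eval()
    with nn.no_grad():
        logits = net(nn.Var(plane[None, None]))
    probs = nn.softmax(logits.data, axis=1)[0]
    labels = probs.argmax(axis=0).astype(np.uint8)
    return probs, labels


def threshold_masks(prob_maps: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Per-class binary masks: probability >= threshold (default 0.5)."""
    return np.asarray(prob_maps) >= threshold


def predict_volume(net: MFUNet, vol: CTVolume) -> LabelVolume:
    """Per-slice prediction stacked back into a volume, spacing preserved."""
    planes = [predict_slice(net, p)[1] for p in vol.slices()]
    return reconstruct_volume(planes, vol.spacing, affine=vol.affine)
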