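"""2D U-Net backbone, pretext heads, weight transfer and bottleneck extraction.

The backbone follows the classic encoder/decoder layout used for slice-wise
CT segmentation: five encoder blocks (two 3x3 convolutions, each followed by
batch-norm and ReLU; channels double across a block) separated by 2x2
max-pooling, and four decoder blocks (kernel-2 stride-2 transposed
convolution, concatenation with the matching encoder skip, then two
convolutions halving the channel count).  With the default 32 base channels
the encoder produces feature maps of 32, 64, 128, 256 and 512 channels and a
256x256 input yields a 16x16x512 bottleneck.

Pretext tasks attach heads at two points:

* the bottleneck, globally average-pooled to a 512-d vector, feeds MLP heads
  (contrastive projection 512-512-128, classifiers 512-1024-256-n);
* a partial decoder (encoder + three decoder blocks, skip connections kept)
  ends in a 64-channel map at half the input resolution, fed to a 1x1
  convolutional projection head 64-128-32 for the local contrastive task.

Weights learned on a pretext task are copied into a fresh full U-Net by
:func:`transfer_weights` under a :class:`TransferScope`; nothing is frozen
afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from enum import Enum

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Checkpoint,
)

__all__ = [
    "UNetSpec",
    "HeadSpec",
    "TransferScope",
    "UNet",
    "ConvBlock",
    "MLPProjectionHead",
    "ConvProjectionHead",
    "ClassifierHead",
    "EncoderWithHead",
    "PartialDecoderWithHead",
    "build_unet",
    "build_head",
    "build_partial_decoder",
    "transfer_weights",
    "extract_bottleneck",
    "backbone_state",
]


@dataclass(frozen=True)
class UNetSpec:
    """Architecture description; defaults match the full-scale network."""

    n_encoder_blocks: int = 5
    n_decoder_blocks: int = 4
    base_channels: int = 32
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self):
        if self.n_encoder_blocks < 2 or self.n_decoder_blocks < 1:
            raise ValueError("need >=2 encoder and >=1 decoder blocks")
        if self.n_decoder_blocks > self.n_encoder_blocks - 1:
            raise ValueError("more decoder blocks than down-sampling steps")

    @property
    def bottleneck_channels(self) -> int:
        return self.base_channels * 2 ** (self.n_encoder_blocks - 1)

    @property
    def downsample_factor(self) -> int:
        return 2 ** (self.n_encoder_blocks - 1)


@dataclass(frozen=True)
class HeadSpec:
    """kind: mlp_projection | conv_projection | classifier; widths include in/out."""

    kind: str
    layer_widths: tuple[int, ...]

    def __post_init__(self):
        if self.kind not in ("mlp_projection", "conv_projection", "classifier"):
            raise ValueError(f"unknown head kind '{self.kind}'")
        if len(self.layer_widths) < 2:
            raise ValueError("layer_widths must list at least input and output")


class TransferScope(Enum):
    ENCODER_ONLY = "encoder_only"
    ENCODER_PLUS_PARTIAL_DECODER = "encoder_plus_partial_decoder"
    FULL_NETWORK = "full_network"

    def prefixes(self, n_partial_decoder_blocks: int = 3) -> tuple[str, ...]:
        if self is TransferScope.ENCODER_ONLY:
            return ("enc.",)
        if self is TransferScope.ENCODER_PLUS_PARTIAL_DECODER:
            pre = ["enc."]
            for j in range(n_partial_decoder_blocks):
                pre += [f"ups.{j}.", f"dec.{j}."]
            return tuple(pre)
        return ("enc.", "ups.", "dec.", "out.")


class ConvBlock(Module):
    """conv(3x3) -> BN -> ReLU -> conv(3x3) -> BN -> ReLU."""

    def __init__(self, in_ch: int, mid_ch: int, out_ch: int, rng: np.random.Generator):
        self.conv1 = Conv2d(in_ch, mid_ch, 3, rng)
        self.bn1 = BatchNorm2d(mid_ch)
        self.act1 = ReLU()
        self.conv2 = Conv2d(mid_ch, out_ch, 3, rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.act2 = ReLU()

    def forward(self, x, training=False):
        x = self.act1(self.bn1(self.conv1(x, training), training), training)
        return self.act2(self.bn2(self.conv2(x, training), training), training)

    def backward(self, dout):
        d = self.conv2.backward(self.bn2.backward(self.act2.backward(dout)))
        return self.conv1.backward(self.bn1.backward(self.act1.backward(d)))


class UNet(Module):
    """Backbone; with ``include_output=False`` it ends at the last decoder block
    (the partial-decoder configuration used by the local contrastive task)."""

    def __init__(self, spec: UNetSpec, rng: np.random.Generator, include_output: bool = True):
        self.spec = spec
        b, ne, nd = spec.base_channels, spec.n_encoder_blocks, spec.n_decoder_blocks
        enc, pools = [], []
        for i in range(ne):
            if i == 0:
                enc.append(ConvBlock(spec.in_channels, b, b, rng))
            else:
                c = b * 2 ** (i - 1)
                enc.append(ConvBlock(c, c, 2 * c, rng))
            if i < ne - 1:
                pools.append(MaxPool2d())
        ups, dec = [], []
        for j in range(nd):
            d = spec.bottleneck_channels // 2**j
            ups.append(ConvTranspose2d(d, d // 2, rng))
            dec.append(ConvBlock(d, d // 2, d // 2, rng))
        self.enc = enc
        self.pools = pools
        self.ups = ups
        self.dec = dec
        self.out = Conv2d(b * 2 ** (ne - 1 - nd), spec.out_channels, 1, rng) if include_output else None

    # -- encoder-only path (classification / global contrastive heads) -----
    def encode(self, x, training=False):
        """Run the encoder; returns the bottleneck map and keeps caches so
        :meth:`encode_backward` can propagate a bottleneck gradient."""
        self._check_input(x)
        skips = []
        h = x
        for i, blk in enumerate(self.enc):
            h = blk(h, training)
            if i < len(self.enc) - 1:
                skips.append(h)
                h = self.pools[i](h, training)
        self._skips = skips
        return h

    def encode_backward(self, dbottleneck, dskips=None):
        d = dbottleneck
        n_enc = len(self.enc)
        for i in reversed(range(n_enc)):
            if i < n_enc - 1:
                d = self.pools[i].backward(d)
                if dskips is not None and dskips[i] is not None:
                    d = d + dskips[i]
            d = self.enc[i].backward(d)
        return d

    def forward(self, x, training=False):
        h = self.encode(x, training)
        self._skip_channels = []
        for j in range(len(self.dec)):
            h = self.ups[j](h, training)
            skip = self._skips[len(self.enc) - 2 - j]
            self._skip_channels.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            h = self.dec[j](h, training)
        if self.out is not None:
            h = self.out(h, training)
        return h

    def backward(self, dout):
        d = self.out.backward(dout) if self.out is not None else dout
        dskips = [None] * (len(self.enc) - 1)
        for j in reversed(range(len(self.dec))):
            d = self.dec[j].backward(d)
            s_ch = self._skip_channels[j]
            dskip, dup = d[:, :s_ch], d[:, s_ch:]
            idx = len(self.enc) - 2 - j
            dskips[idx] = dskip if dskips[idx] is None else dskips[idx] + dskip
            d = self.ups[j].backward(dup)
        return self.encode_backward(d, dskips)

    def _check_input(self, x):
        f = self.spec.downsample_factor
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise ValueError(f"expected NCHW input with {self.spec.in_channels} channel(s)")
        if x.shape[2] % f or x.shape[3] % f:
            raise ValueError(
                f"spatial size {x.shape[2]}x{x.shape[3]} not divisible by {f}"
            )

    def predict_proba(self, x):
        """Sigmoid of the output logits (evaluation mode)."""
        logits = self.forward(x, training=False)
        return 1.0 / (1.0 + np.exp(-logits))


class MLPProjectionHead(Module):
    """Global average pool then a 2-layer MLP (e.g. 512 -> 512 -> 128)."""

    def __init__(self, widths: tuple[int, ...], rng: np.random.Generator):
        if len(widths) != 3:
            raise ValueError("mlp_projection takes (in, hidden, out) widths")
        self.pool = GlobalAvgPool()
        self.fc1 = Linear(widths[0], widths[1], rng)
        self.act = ReLU()
        self.fc2 = Linear(widths[1], widths[2], rng)

    def forward(self, x, training=False):
        return self.fc2(self.act(self.fc1(self.pool(x, training), training), training), training)

    def backward(self, dout):
        d = self.fc1.backward(self.act.backward(self.fc2.backward(dout)))
        return self.pool.backward(d)


class ConvProjectionHead(Module):
    """Series of 1x1 convolutions on a decoder feature map (e.g. 64 -> 128 -> 32)."""

    def __init__(self, widths: tuple[int, ...], rng: np.random.Generator):
        if len(widths) != 3:
            raise ValueError("conv_projection takes (in, hidden, out) widths")
        self.conv1 = Conv2d(widths[0], widths[1], 1, rng)
        self.act = ReLU()
        self.conv2 = Conv2d(widths[1], widths[2], 1, rng)

    def forward(self, x, training=False):
        return self.conv2(self.act(self.conv1(x, training), training), training)

    def backward(self, dout):
        return self.conv1.backward(self.act.backward(self.conv2.backward(dout)))


class ClassifierHead(Module):
    """Global average pool then an MLP ending in n-class logits
    (softmax or sigmoid is applied by the loss / prediction code)."""

    def __init__(self, widths: tuple[int, ...], rng: np.random.Generator):
        self.pool = GlobalAvgPool()
        self.fcs = [Linear(widths[i], widths[i + 1], rng) for i in range(len(widths) - 1)]
        self.acts = [ReLU() for _ in range(len(widths) - 2)]

    def forward(self, x, training=False):
        h = self.pool(x, training)
        for i, fc in enumerate(self.fcs):
            h = fc(h, training)
            if i < len(self.acts):
                h = self.acts[i](h, training)
        return h

    def backward(self, dout):
        d = dout
        for i in reversed(range(len(self.fcs))):
            if i < len(self.acts):
                d = self.acts[i].backward(d)
            d = self.fcs[i].backward(d)
        return self.pool.backward(d)


class EncoderWithHead(Module):
    """U-Net encoder followed by a pooled head (projection or classifier)."""

    def __init__(self, backbone: UNet, head: Module):
        self.backbone = backbone
        self.head = head

    def forward(self, x, training=False):
        return self.head(self.backbone.encode(x, training), training)

    def backward(self, dout):
        return self.backbone.encode_backward(self.head.backward(dout))


class PartialDecoderWithHead(Module):
    """Encoder + three decoder blocks (skips kept) + 1x1 conv projection head."""

    def __init__(self, backbone: UNet, head: ConvProjectionHead):
        if backbone.out is not None:
            raise ValueError("partial backbone must be built with include_output=False")
        self.backbone = backbone
        self.head = head

    def forward(self, x, training=False):
        return self.head(self.backbone(x, training), training)

    def backward(self, dout):
        return self.backbone.backward(self.head.backward(dout))


def build_unet(spec: UNetSpec | None = None, seed: int = 0) -> UNet:
    """Freshly initialized full U-Net (Kaiming-uniform, seeded)."""
    return UNet(spec or UNetSpec(), np.random.default_rng(seed))


def build_head(spec: HeadSpec, seed: int = 0) -> Module:
    rng = np.random.default_rng(seed)
    w = tuple(spec.layer_widths)
    if spec.kind == "mlp_projection":
        return MLPProjectionHead(w, rng)
    if spec.kind == "conv_projection":
        return ConvProjectionHead(w, rng)
    return ClassifierHead(w, rng)


def build_partial_decoder(
    backbone: UNet,
    head_spec: HeadSpec | None = None,
    n_decoder_blocks: int = 3,
    seed: int = 0,
) -> PartialDecoderWithHead:
    """Partial network for the local contrastive task: the encoder of
    ``backbone`` plus ``n_decoder_blocks`` decoder blocks, topped by a 1x1
    convolutional projection head.  Encoder (and any already-present decoder)
    weights are copied from ``backbone``; the head is fresh."""
    spec = backbone.spec
    partial_spec = UNetSpec(
        n_encoder_blocks=spec.n_encoder_blocks,
        n_decoder_blocks=n_decoder_blocks,
        base_channels=spec.base_channels,
        in_channels=spec.in_channels,
        out_channels=spec.out_channels,
    )
    rng = np.random.default_rng(seed)
    partial = UNet(partial_spec, rng, include_output=False)
    feat_ch = spec.bottleneck_channels // 2**n_decoder_blocks
    if head_spec is None:
        head_spec = HeadSpec("conv_projection", (feat_ch, 2 * feat_ch, spec.base_channels))
    if head_spec.layer_widths[0] != feat_ch:
        raise ValueError(
            f"head input width {head_spec.layer_widths[0]} != feature channels {feat_ch}"
        )
    # inherit the source backbone's weights on the shared subgraph
    src = backbone.state_dict()
    shared = {
        k: v
        for k, v in src.items()
        if any(k.startswith(p) for p in TransferScope.ENCODER_PLUS_PARTIAL_DECODER.prefixes(n_decoder_blocks))
    }
    partial.load_state_dict(shared, strict=False)
    return PartialDecoderWithHead(partial, build_head(head_spec, seed=seed + 1))


def backbone_state(net: Module) -> dict[str, np.ndarray]:
    """State dict rooted at the U-Net backbone (strips a ``backbone.`` prefix)."""
    state = net.state_dict()
    if any(k.startswith("backbone.") for k in state):
        return {
            k[len("backbone."):]: v for k, v in state.items() if k.startswith("backbone.")
        }
    return state


def transfer_weights(
    source: Checkpoint | Module | dict,
    target: UNet,
    scope: TransferScope,
) -> UNet:
    """Copy in-scope parameter groups from ``source`` into ``target``.

    ``source`` may be a checkpoint, a module, or a backbone-rooted state
    dict.  Tensors outside the scope keep the target's fresh initialization;
    no tensor is frozen.  A shape mismatch on an in-scope tensor raises a
    ``ValueError`` naming the tensor.
    """
    if isinstance(source, Checkpoint):
        state = source.state
    elif isinstance(source, Module):
        state = backbone_state(source)
    else:
        state = source
    prefixes = scope.prefixes()
    own = target.state_dict()
    copied = {}
    for key, arr in state.items():
        if not any(key.startswith(p) for p in prefixes):
            continue
        if key not in own:
            continue
        if own[key].shape != arr.shape:
            raise ValueError(
                f"transfer shape mismatch on '{key}': {own[key].shape} vs {arr.shape}"
            )
        copied[key] = arr
    target.load_state_dict(copied, strict=False)
    return target


def extract_bottleneck(network: UNet, image: np.ndarray) -> np.ndarray:
    """Average-pooled bottleneck representation of one 2D image.

    For the default architecture this is the 512-dimensional vector used to
    inspect what a pretext task has learned (e.g. via t-SNE downstream).
    """
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[:, None]
    bott = network.encode(x, training=False)
    vec = bott.mean(axis=(2, 3))
    return vec[0] if image.ndim == 2 else vec


def spec_to_dict(spec: UNetSpec) -> dict:
    return asdict(spec)
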