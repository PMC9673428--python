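"""Serial dual encoder-decoder segmentation network (SCU-Net).

Two VGG16-style encoder-decoder structures run in series: the first
decoder's full-resolution output (``up1``) is the second encoder's input,
and every layer of the second structure is additionally concatenated with
the same-layer activation of the first structure, followed by two 3x3
convolutions that recover the layer width.  Encoders use hybrid-dilated-
convolution groups instead of plain convolutions; decoders upsample with
stride-2 transposed convolutions.

Activation naming (five layers, defaults 512x512 input,
widths 64/128/256/512/512):

==========  =====================================  ================
name        produced by                            shape (C, H, W)
==========  =====================================  ================
feature1-5  encoder-1 HDC groups (pool between)    64@512 .. 512@32
up4..up1    decoder-1 upsample+skip+2 convs        512@64 .. 64@512
feature6    encoder-2 HDC group on up1             64@512
feature7'-  encoder-2 HDC groups                   128@256 .. 512@32
feature10'
feature7-   concat with feature2..feature5,        128@256 .. 512@32
feature10   two 3x3 convs
up9'..up7'  decoder-2 upsample+skip+2 convs        512@64 .. 128@256
up9..up7    concat with up4..up2, two 3x3 convs    512@64 .. 128@256
up6         top decoder-2 stage (skip = feature6)  64@512
==========  =====================================  ================

Layer 5 is the bottleneck: no up5/up10 activations exist.  The final head
is a 1x1 convolution to ``num_classes`` followed by a per-pixel softmax.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .hdc import HDCSchedule, HDCGroup, DEFAULT_SCHEDULE
from .nn.tensor import Tensor, concat

__all__ = ["ScuNetConfig", "SCUNet", "ShapeTable", "shape_summary"]


@dataclass(frozen=True)
class ScuNetConfig:
    input_size: tuple[int, int] = (512, 512)
    in_channels: int = 3
    layer_widths: tuple[int, ...] = (64, 128, 256, 512, 512)
    num_classes: int = 4
    hdc: HDCSchedule = DEFAULT_SCHEDULE
    upconv_kernel: int = 4

    def __post_init__(self):
        object.__setattr__(self, "input_size", tuple(self.input_size))
        object.__setattr__(self, "layer_widths", tuple(self.layer_widths))
        if len(self.layer_widths) != 5:
            raise ValueError("layer_widths must list exactly 5 widths")
        h, w = self.input_size
        if h % 16 or w % 16:
            raise ValueError(
                f"input size {h}x{w} must be divisible by 16 "
                "(four 2x2 pooling stages)")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.upconv_kernel not in (3, 4):
            raise ValueError("upconv_kernel must be 3 or 4")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hdc"] = {"kernel_size": self.hdc.kernel_size,
                    "rates": list(self.hdc.rates),
                    "paddings": list(self.hdc.paddings)}
        d["input_size"] = list(self.input_size)
        d["layer_widths"] = list(self.layer_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScuNetConfig":
        d = dict(d)
        if "hdc" in d and isinstance(d["hdc"], dict):
            h = d["hdc"]
            d["hdc"] = HDCSchedule(
                kernel_size=h.get("kernel_size", h.get("kernel", 3)),
                rates=tuple(h.get("rates", (1, 2, 3))),
                paddings=tuple(h["paddings"]) if h.get("paddings") else None)
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


ShapeTable = list  # of (name, channels, height, width)


def _up_params(kernel: int) -> dict:
    """stride-2 transposed-conv settings giving an exact x2 upsample."""
    if kernel == 4:
        return dict(stride=2, padding=1, output_padding=0)
    return dict(stride=2, padding=1, output_padding=1)  # kernel 3


class _TwoConvs(nn.Module):
    """concat-recovery block: two 3x3 conv+BN+ReLU, in_ch -> out_ch."""

    def __init__(self, in_ch: int, out_ch: int, *, rng, dtype=np.float32):
        self.c1 = nn.Conv2d(in_ch, out_ch, 3, padding=1, rng=rng, dtype=dtype)
        self.n1 = nn.BatchNorm2d(out_ch, dtype=dtype)
        self.c2 = nn.Conv2d(out_ch, out_ch, 3, padding=1, rng=rng, dtype=dtype)
        self.n2 = nn.BatchNorm2d(out_ch, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        x = self.n1(self.c1(x)).relu()
        return self.n2(self.c2(x)).relu()


class _Encoder(nn.Module):
    """Five HDC groups with 2x2 max pooling between layers."""

    def __init__(self, in_ch: int, widths, schedule, *, rng, dtype=np.float32):
        self.groups = [HDCGroup(in_ch if i == 0 else widths[i - 1], widths[i],
                                schedule, rng=rng, dtype=dtype)
                       for i in range(5)]

    def forward(self, x: Tensor) -> list[Tensor]:
        feats = []
        for i, group in enumerate(self.groups):
            if i > 0:
                x = nn.max_pool2d(x, 2)
            x = group(x)
            feats.append(x)
        return feats


class _DecoderStage(nn.Module):
    """transposed-conv x2 upsample, concat same-layer skip, two 3x3 convs."""

    def __init__(self, in_ch: int, skip_ch: int, out_ch: int, upconv_kernel: int,
                 *, rng, dtype=np.float32):
        self.up = nn.ConvTranspose2d(in_ch, out_ch, upconv_kernel,
                                     rng=rng, dtype=dtype,
                                     **_up_params(upconv_kernel))
        self.fuse = _TwoConvs(out_ch + skip_ch, out_ch, rng=rng, dtype=dtype)

    def forward(self, below: Tensor, skip: Tensor) -> Tensor:
        u = self.up(below)
        if u.data.shape[2:] != skip.data.shape[2:]:
            raise ValueError(
                f"skip resolution {skip.data.shape} does not match upsampled "
                f"map {u.data.shape}")
        return self.fuse(concat([u, skip], axis=1))


class SCUNet(nn.Module):
    """The serial dual encoder-decoder network.

    Parameters
    ----------
    config : ScuNetConfig
    seed : int, parameter-initialisation seed (He-uniform weights).
    """

    def __init__(self, config: ScuNetConfig = ScuNetConfig(), *, seed: int = 0,
                 dtype=np.float32):
        rng = np.random.default_rng(seed)
        w = config.layer_widths
        k = config.upconv_kernel
        self.config = config
        self.encoder1 = _Encoder(config.in_channels, w, config.hdc,
                                 rng=rng, dtype=dtype)
        self.decoder1 = [
            _DecoderStage(w[i + 1] if i < 3 else w[4], w[i], w[i], k,
                          rng=rng, dtype=dtype)
            for i in range(3, -1, -1)            # layers 4,3,2,1 -> up4..up1
        ]
        self.encoder2 = _Encoder(w[0], w, config.hdc, rng=rng, dtype=dtype)
        # cross-network recovery convs on the encoder side (layers 2..5)
        self.enc_fuse = [_TwoConvs(2 * w[i], w[i], rng=rng, dtype=dtype)
                         for i in range(1, 5)]
        self.decoder2 = [
            _DecoderStage(w[i + 1] if i < 3 else w[4], w[i], w[i], k,
                          rng=rng, dtype=dtype)
            for i in range(3, -1, -1)
        ]
        # cross-network recovery convs on the decoder side (layers 2..4)
        self.dec_fuse = [_TwoConvs(2 * w[i], w[i], rng=rng, dtype=dtype)
                         for i in range(1, 4)]
        self.head = nn.Conv2d(w[0], config.num_classes, 1, rng=rng, dtype=dtype)

    # -- pieces ------------------------------------------------------------

    def _check_input(self, x: Tensor) -> Tensor:
        if isinstance(x, np.ndarray):
            x = Tensor(x)
        if x.ndim == 2:
            x = x.reshape(1, 1, *x.shape)
        elif x.ndim == 3:
            x = x.reshape(1, *x.shape)
        n, c, h, w = x.data.shape
        if c == 1 and self.config.in_channels == 3:
            # grayscale input replicated onto three channels
            x = concat([x, x, x], axis=1)
        elif c != self.config.in_channels:
            raise ValueError(f"expected {self.config.in_channels} channels, got {c}")
        if h % 16 or w % 16:
            raise ValueError(f"input {h}x{w} must be divisible by 16")
        return x

    def forward_encoder(self, image) -> list[Tensor]:
        """feature1..feature5 of the first encoder."""
        return self.encoder1(self._check_input(image))

    def forward_decoder(self, features: list[Tensor],
                        extra_skips: list[Tensor] | None = None,
                        *, second: bool = False):
        """Run a decoder over five same-layer feature maps.

        ``features`` are the layer-1..5 maps (layer 5 = bottleneck).  For the
        second decoder, ``extra_skips`` are decoder-1's up2..up4 used in the
        cross-network concatenations; the classification head is applied only
        there.  Returns the ups in order of computation (deep to shallow).
        """
        stages = self.decoder2 if second else self.decoder1
        x = features[4]
        ups = []
        for idx, stage in enumerate(stages):       # idx 0..3 -> layers 4..1
            layer = 4 - idx
            u = stage(x, features[layer - 1])      # primed up in decoder 2
            if second and layer >= 2:
                u = self.dec_fuse[layer - 2](
                    concat([u, extra_skips[layer - 2]], axis=1))
            ups.append(u)
            x = u
        return ups

    # -- full pass ---------------------------------------------------------

    def forward(self, image, *, return_activations: bool = False):
        """Per-pixel class probabilities (N, num_classes, H, W)."""
        x = self._check_input(image)
        acts: dict[str, Tensor] = {}

        feats1 = self.encoder1(x)                       # feature1..feature5
        for i, f in enumerate(feats1, start=1):
            acts[f"feature{i}"] = f

        ups1 = self.forward_decoder(feats1)             # up4..up1
        for layer, u in zip(range(4, 0, -1), ups1):
            acts[f"up{layer}"] = u
        up1 = ups1[-1]

        # encoder 2 with cross-network concatenation at layers 2..5
        feats2 = []
        y = up1
        for i, group in enumerate(self.encoder2.groups):
            if i > 0:
                y = nn.max_pool2d(y, 2)
            y = group(y)
            if i == 0:
                acts["feature6"] = y
            else:
                acts[f"feature{6 + i}'"] = y            # feature7'..feature10'
                y = self.enc_fuse[i - 1](concat([y, feats1[i]], axis=1))
                acts[f"feature{6 + i}"] = y             # feature7..feature10
            feats2.append(y)

        # decoder 2: skips are feature6..feature10; cross skips are up2..up4
        x2 = feats2[4]
        for idx, stage in enumerate(self.decoder2):     # layers 4..1
            layer = 4 - idx
            u = stage(x2, feats2[layer - 1])
            if layer >= 2:
                acts[f"up{layer + 5}'"] = u             # up9'..up7'
                u = self.dec_fuse[layer - 2](
                    concat([u, acts[f"up{layer}"]], axis=1))
                acts[f"up{layer + 5}"] = u              # up9..up7
            else:
                acts["up6"] = u
            x2 = u

        logits = self.head(x2)
        probs = logits.softmax(axis=1)
        acts["probabilities"] = probs
        if return_activations:
            return probs, acts
        return probs

    def predict_proba(self, image) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            return self.forward(image).data
        finally:
            if was_training:
                self.train()


def shape_summary(config: ScuNetConfig = ScuNetConfig()) -> ShapeTable:
    """Analytic (channels, H, W) of every named activation — no forward pass."""
    h, w = config.input_size
    widths = config.layer_widths
    nc = config.num_classes
    table: ShapeTable = []
    res = [(h >> i, w >> i) for i in range(5)]      # layer 1..5 resolutions

    for i in range(5):                               # feature1..feature5
        table.append((f"feature{i + 1}", widths[i], *res[i]))
    for layer in range(4, 0, -1):                    # up4..up1
        table.append((f"up{layer}", widths[layer - 1], *res[layer - 1]))
    table.append(("feature6", widths[0], *res[0]))
    for i in range(1, 5):                            # layers 2..5 of encoder 2
        table.append((f"feature{6 + i}'", widths[i], *res[i]))
        table.append((f"feature{6 + i}", widths[i], *res[i]))
    for layer in range(4, 1, -1):                    # up9'/up9 .. up7'/up7
        table.append((f"up{layer + 5}'", widths[layer - 1], *res[layer - 1]))
        table.append((f"up{layer + 5}", widths[layer - 1], *res[layer - 1]))
    table.append(("up6", widths[0], *res[0]))
    table.append(("probabilities", nc, h, w))
    return table


def format_shape_table(table: ShapeTable) -> str:
    lines = [f"{'activation':<14}{'channels':>9}{'height':>8}{'width':>7}"]
    for name, c, hh, ww in table:
        lines.append(f"{name:<14}{c:>9}{hh:>8}{ww:>7}")
    return "\n".join(lines)
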