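"""The weakly-supervised stone detection network.

Composition (all stride-1 convolutions, pooling does the downsampling):

* a VGG-style feature backbone (two 2x2 stride-2 max pools, so the deep
  feature ``f_b`` lives at 1/4 resolution) with dropout after each block;
* a multiple field-of-view encoder: four cascaded 3x3 dilated convolutions
  (rates 1, 2, 4, 8; each later stage sees ``f_b`` concatenated with the
  previous dilated feature) plus a 2x2 max-pooled copy of ``f_b``, all
  concatenated into the encoder feature ``f_E``;
* an upsampling decoder (two bilinear x2 stages and three 3x3 conv +
  instance-norm layers, then a 1x1 conv to 64 channels) producing the
  full-resolution decoder feature ``f_U``; global-average-pooled backbone
  block features multiply the first two stages channel-wise ("forward
  connections");
* a CBAM-style attention head: channel attention ``m_c`` (sigmoid of
  spatial max + mean per channel), spatial attention ``m_s`` (7x7 conv over
  channel max/mean maps, sigmoid), and the probability map
  ``m_p = sigmoid(conv1x1(m_s * (m_c * f_U)))``;
* a classifier on the flattened probability map: two 256-unit fully
  connected layers and a 2-way softmax; ``y_hat`` is the stone probability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .errors import ConfigError, ValidationError

__all__ = ["ModelConfig", "ModelOutputs", "StoneDetector", "count_parameters"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; the defaults are the full-width model."""

    image_size: int = 96
    backbone_channels: tuple[int, ...] = (64, 128, 256)
    convs_per_block: int = 2
    dropout: float = 0.3
    c_d: int = 64
    dilation_rates: tuple[int, ...] = (1, 2, 4, 8)
    pool_mode: str = "stride1"  # how f_p keeps f_b's resolution: stride1 | downup
    decoder_channels: tuple[int, int, int] = (64, 64, 64)
    f_u_channels: int = 64
    classifier_hidden: int = 256
    classifier_pool: int | None = None  # optional average-pool side before flatten
    use_mfov: bool = True
    use_channel_attention: bool = True
    use_spatial_attention: bool = True
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self):
        if self.image_size % 4:
            raise ConfigError("image_size must be divisible by 4 (two 2x2 pools)")
        if len(self.backbone_channels) != 3 or any(c < 1 for c in self.backbone_channels):
            raise ConfigError("backbone_channels must be three positive counts")
        rates = self.dilation_rates
        if list(rates) != sorted(set(rates)) or any(r < 1 for r in rates):
            raise ConfigError("dilation rates must be strictly increasing positive integers")
        if self.pool_mode not in ("stride1", "downup"):
            raise ConfigError(f"unknown pool_mode {self.pool_mode!r}")
        if self.dtype not in ("float32", "float64"):
            raise ConfigError("dtype must be float32 or float64")
        if self.classifier_pool is not None and self.image_size % self.classifier_pool:
            raise ConfigError("classifier_pool must divide image_size")

    @property
    def np_dtype(self):
        return np.float32 if self.dtype == "float32" else np.float64

    @property
    def encoder_channels(self) -> int:
        cb = self.backbone_channels[-1]
        return len(self.dilation_rates) * self.c_d + cb if self.use_mfov else cb

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("backbone_channels", "dilation_rates", "decoder_channels"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for k in ("backbone_channels", "dilation_rates", "decoder_channels"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class ModelOutputs:
    """Every intermediate a loss or the localizer may need."""

    f_b: Tensor
    block1: Tensor
    block2: Tensor
    f_d: tuple[Tensor, ...] | None
    f_p: Tensor | None
    f_E: Tensor
    f_U: Tensor
    m_c: Tensor  # (N, C) channel attention
    m_s: Tensor  # (N, 1, H, W) spatial attention
    m_p: Tensor  # (N, 1, H, W) probability map
    logits: Tensor  # (N, 2)
    y_hat: Tensor  # (N,) stone probability


def _gap(x) -> Tensor:
    """Spatial-wise global average pooling, keeping the (N, C, 1, 1) shape."""
    return ad.reduce_mean(x, axis=(2, 3), keepdims=True)


class StoneDetector(nn.Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        dt = config.np_dtype
        rng = np.random.default_rng(config.seed)
        self._drop_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(1)[0]
        )
        self.training = True

        # --- backbone -----------------------------------------------------
        self.backbone_convs: list[list[nn.Conv2d]] = []
        in_ch = 1
        for b, ch in enumerate(config.backbone_channels):
            block = []
            for c in range(config.convs_per_block):
                conv = nn.Conv2d(in_ch, ch, 3, rng=rng, dtype=dt)
                self.add_child(f"backbone.b{b + 1}.conv{c + 1}", conv)
                block.append(conv)
                in_ch = ch
            self.backbone_convs.append(block)

        # --- multiple field-of-view encoder -------------------------------
        cb = config.backbone_channels[-1]
        self.mfov_convs: list[nn.Conv2d] = []
        if config.use_mfov:
            for k, rate in enumerate(config.dilation_rates):
                cin = cb if k == 0 else cb + config.c_d
                conv = nn.Conv2d(cin, config.c_d, 3, dilation=rate, rng=rng, dtype=dt)
                self.add_child(f"mfov.d{rate}", conv)
                self.mfov_convs.append(conv)

        # --- decoder -------------------------------------------------------
        d1, d2, d3 = config.decoder_channels
        self.dec1 = self.add_child("decoder.conv1", nn.Conv2d(config.encoder_channels, d1, 3, rng=rng, dtype=dt, bias=False))
        self.in1 = self.add_child("decoder.in1", nn.InstanceNorm2d(d1, dtype=dt))
        self.dec2 = self.add_child("decoder.conv2", nn.Conv2d(d1, d2, 3, rng=rng, dtype=dt, bias=False))
        self.in2 = self.add_child("decoder.in2", nn.InstanceNorm2d(d2, dtype=dt))
        self.dec3 = self.add_child("decoder.conv3", nn.Conv2d(d2, d3, 3, rng=rng, dtype=dt, bias=False))
        self.in3 = self.add_child("decoder.in3", nn.InstanceNorm2d(d3, dtype=dt))
        self.dec_out = self.add_child("decoder.out", nn.Conv2d(d3, config.f_u_channels, 1, rng=rng, dtype=dt))
        # forward connections: GAP(block2) -> 1x1 conv -> weights on stage 1
        # (zero weights + unit bias, i.e. identity at initialization);
        # GAP(block1) multiplies stage 2 directly when dimensions agree.
        self.conn2 = self.add_child(
            "decoder.conn2",
            nn.Conv2d(config.backbone_channels[1], d1, 1, dtype=dt, zero_init=True, bias_init=1.0),
        )
        self.conn1 = None
        if config.backbone_channels[0] != d2:
            self.conn1 = self.add_child(
                "decoder.conn1",
                nn.Conv2d(config.backbone_channels[0], d2, 1, dtype=dt, zero_init=True, bias_init=1.0),
            )

        # --- attention head ------------------------------------------------
        # small-gain init so m_s and m_p start near the neutral 0.5 and get
        # their structure from the losses rather than the random projection
        self.spatial_conv = self.add_child("attn.spatial", nn.Conv2d(2, 1, 7, rng=rng, dtype=dt))
        self.spatial_conv.weight.data *= 0.1
        self.prob_conv = self.add_child("attn.prob", nn.Conv2d(config.f_u_channels, 1, 1, rng=rng, dtype=dt))
        self.prob_conv.weight.data *= 0.1

        # --- classifier ----------------------------------------------------
        side = config.classifier_pool or config.image_size
        hidden = config.classifier_hidden
        self.fc1 = self.add_child("cls.fc1", nn.Linear(side * side, hidden, rng=rng, dtype=dt))
        self.fc2 = self.add_child("cls.fc2", nn.Linear(hidden, hidden, rng=rng, dtype=dt))
        self.fc3 = self.add_child("cls.fc3", nn.Linear(hidden, 2, rng=rng, dtype=dt))

    # ---- mode handling ---------------------------------------------------
    def train(self) -> None:
        self.training = True

    def eval(self) -> None:
        self.training = False

    def reseed_dropout(self, seed: int) -> None:
        self._drop_rng = np.random.default_rng(seed)

    # ---- stages ----------------------------------------------------------
    def _as_input(self, image) -> Tensor:
        arr = image.data if isinstance(image, Tensor) else np.asarray(image)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValidationError(f"expected (H, W) or (N, H, W) input, got {arr.shape}")
        H, W = arr.shape[1:]
        if H % 4 or W % 4:
            raise ValidationError(f"spatial size {H}x{W} not divisible by 4")
        return Tensor(arr[:, None].astype(self.config.np_dtype))

    def backbone_forward(self, image) -> tuple[Tensor, Tensor, Tensor]:
        """Run the VGG-style blocks; returns (f_b, block1, block2)."""
        x = self._as_input(image) if not (isinstance(image, Tensor) and image.ndim == 4) else image
        feats = []
        for b, block in enumerate(self.backbone_convs):
            for conv in block:
                x = ad.relu(conv(x))
            x = nn.dropout(x, self.config.dropout, self._drop_rng, self.training)
            feats.append(x)
            if b < 2:
                x = ad.maxpool2x2(x, stride=2)
        return feats[2], feats[0], feats[1]

    def mfov_forward(self, f_b: Tensor) -> tuple[tuple[Tensor, ...] | None, Tensor | None, Tensor]:
        """Cascaded dilated features + pooled feature -> encoder feature f_E.

        Returns (f_d tuple, f_p, f_E); with use_mfov=False the encoder is
        bypassed and f_E is f_b itself.
        """
        if not self.config.use_mfov:
            return None, None, f_b
        feats: list[Tensor] = []
        for k, conv in enumerate(self.mfov_convs):
            inp = f_b if k == 0 else ad.concat([f_b, feats[-1]], axis=1)
            feats.append(ad.relu(conv(inp)))
        if self.config.pool_mode == "stride1":
            f_p = ad.maxpool2x2(f_b, stride=1)
        else:
            f_p = ad.upsample2x_bilinear(ad.maxpool2x2(f_b, stride=2))
        f_E = ad.concat(feats + [f_p], axis=1)
        return tuple(feats), f_p, f_E

    def decoder_forward(self, f_E: Tensor, block1: Tensor, block2: Tensor,
                        connections: bool = True) -> Tensor:
        """Upsample f_E back to full resolution -> f_U (N, 64, H, W)."""
        if f_E.shape[2] * 2 != block2.shape[2] or block2.shape[2] * 2 != block1.shape[2]:
            raise ValidationError(
                f"decoder inputs disagree spatially: f_E {f_E.shape}, "
                f"block2 {block2.shape}, block1 {block1.shape}"
            )
        s1 = ad.relu(self.in1(self.dec1(ad.upsample2x_bilinear(f_E))))
        if connections:
            s1 = s1 * self.conn2(_gap(block2))
        s2 = ad.relu(self.in2(self.dec2(ad.upsample2x_bilinear(s1))))
        if connections:
            w1 = _gap(block1)
            if self.conn1 is not None:
                w1 = self.conn1(w1)
            s2 = s2 * w1
        s3 = ad.relu(self.in3(self.dec3(s2)))
        return ad.relu(self.dec_out(s3))

    def channel_attention(self, f_U: Tensor) -> Tensor:
        """m_c = sigmoid(spatial max + spatial mean), per channel; (N, C)."""
        if not self.config.use_channel_attention:
            return Tensor(np.ones(f_U.shape[:2], dtype=f_U.dtype))
        pre = ad.reduce_max(f_U, axis=(2, 3)) + ad.reduce_mean(f_U, axis=(2, 3))
        return ad.sigmoid(pre)

    def spatial_attention(self, f_U: Tensor) -> Tensor:
        """m_s = sigmoid(conv7x7(channel max ++ channel mean)); (N, 1, H, W)."""
        if not self.config.use_spatial_attention:
            return Tensor(np.ones((f_U.shape[0], 1) + f_U.shape[2:], dtype=f_U.dtype))
        cmax = ad.reduce_max(f_U, axis=1, keepdims=True)
        cmean = ad.reduce_mean(f_U, axis=1, keepdims=True)
        return ad.sigmoid(self.spatial_conv(ad.concat([cmax, cmean], axis=1)))

    def attended_feature(self, f_U: Tensor, m_c: Tensor, m_s: Tensor) -> Tensor:
        """m_s * (m_c * f_U), the shared operand of m_p and the stone map."""
        mc = ad.reshape(m_c, m_c.shape + (1, 1))
        return m_s * (mc * f_U)

    def probability_map(self, f_U: Tensor, m_c: Tensor, m_s: Tensor) -> Tensor:
        """m_p = sigmoid(conv1x1(m_s * (m_c * f_U))); (N, 1, H, W)."""
        return ad.sigmoid(self.prob_conv(self.attended_feature(f_U, m_c, m_s)))

    def classify(self, m_p: Tensor) -> tuple[Tensor, Tensor]:
        """Two hidden FC layers + 2-way softmax on the flattened m_p."""
        N = m_p.shape[0]
        x = m_p
        side = self.config.classifier_pool
        if side is not None:
            H = m_p.shape[2]
            f = H // side
            x = ad.reduce_mean(
                ad.reshape(x, (N, 1, side, f, side, f)), axis=(3, 5)
            )
        x = ad.reshape(x, (N, int(np.prod(x.shape[1:]))))
        if x.shape[1] != self.fc1.weight.shape[0]:
            raise ValidationError(
                f"classifier was built for {self.fc1.weight.shape[0]} inputs, got {x.shape[1]}"
            )
        h = ad.relu(self.fc1(x))
        h = ad.relu(self.fc2(h))
        logits = self.fc3(h)
        zmax = ad.reduce_max(logits, axis=1, keepdims=True)
        e = ad.exp(logits - zmax)
        probs = e / ad.reduce_sum(e, axis=1, keepdims=True)
        return logits, probs[:, 1]

    def forward(self, image) -> ModelOutputs:
        """Full pass; returns every intermediate for losses and inspection."""
        x = self._as_input(image)
        if x.shape[2] != self.config.image_size or x.shape[3] != self.config.image_size:
            raise ValidationError(
                f"model built for {self.config.image_size}px inputs, got {x.shape[2:]}"
            )
        f_b, block1, block2 = self.backbone_forward(x)
        f_d, f_p, f_E = self.mfov_forward(f_b)
        f_U = self.decoder_forward(f_E, block1, block2)
        m_c = self.channel_attention(f_U)
        m_s = self.spatial_attention(f_U)
        m_p = self.probability_map(f_U, m_c, m_s)
        logits, y_hat = self.classify(m_p)
        return ModelOutputs(f_b, block1, block2, f_d, f_p, f_E, f_U,
                            m_c, m_s, m_p, logits, y_hat)

    __call__ = forward

    # ---- persistence ----------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"param/{k}": v for k, v in self.state_dict().items()}
        np.savez(
            Path(path),
            __config__=np.frombuffer(
                json.dumps(self.config.to_dict()).encode(), dtype=np.uint8
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "StoneDetector":
        with np.load(Path(path)) as data:
            cfg = ModelConfig.from_dict(
                json.loads(bytes(data["__config__"].tobytes()).decode())
            )
            model = cls(cfg)
            model.load_state_dict(
                {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
            )
        return model


def count_parameters(config: ModelConfig) -> int:
    """Total trainable parameter count (a deterministic function of config)."""
    return StoneDetector(config).n_parameters()
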