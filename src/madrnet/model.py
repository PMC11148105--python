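"""Assembly of the full multi-level attention dilated residual network.

The network is a U-Net-shaped encoder-decoder:

* **Encoder** — an initial 1x1 convolution (L1) that lifts the image into
  feature space without spatial mixing, then six multi-dilated residual
  blocks following the channel progression 32 -> 64 -> 128 -> 256 -> 512 ->
  1024, with 2x2 max pooling between the first five blocks and the next
  stage.  Registry entries L1..L12 (1 conv + 6 blocks + 5 pools).
* **Bottleneck** — atrous spatial pyramid pooling at the deepest resolution
  (L13), 1024 channels in and out.
* **Decoder** — five stages (L14..L33), each: 2x2 transposed-convolution
  upsampling, channel-spatial attention applied to the resolution-matched
  encoder feature, channel concatenation, and a multi-dilated residual
  block.  The stage/skip couplings are (L14, L10), (L18, L8), (L22, L6),
  (L26, L4), (L30, L2).
* **Head** — the final decoder feature is combined with the L1 feature
  (channel concatenation by default), passed through a second, narrow ASPP,
  and classified by a 1x1 convolution (L34..L36) with a sigmoid (binary) or
  per-pixel softmax (multiclass) activation (L37).

The registry convention counts one entry per macro-layer and is chosen so
the encoder has 12 entries, the decoder-plus-head 23, and the whole network
37.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor
from .blocks import ASPP, AttentionConfig, CSAM, MultiDilatedResidualBlock

DEFAULT_CHANNELS = (32, 64, 128, 256, 512, 1024)


@dataclass
class ModelConfig:
    """Every architectural knob of the network.

    ``channel_progression`` lists the output width of each encoder residual
    block; successive widths must double.  ``input_size`` must be divisible
    by ``2**depth`` (depth = number of pooling stages = len(progression)-1).
    """

    in_channels: int = 3
    num_classes: int = 1
    input_size: int = 128
    channel_progression: tuple[int, ...] = DEFAULT_CHANNELS
    block_rates: tuple[int, ...] = (1, 3, 5, 11)
    convs_per_branch: int = 2
    aspp_rates: tuple[int, ...] = (6, 12, 18)
    aspp_pool_mode: str = "avg"
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    head_activation: str = "auto"  # auto | sigmoid | softmax
    head_width: int = 32
    l1_merge: str = "concat"  # concat | add
    seed: int = 0

    def __post_init__(self):
        self.channel_progression = tuple(int(c) for c in self.channel_progression)
        self.block_rates = tuple(int(r) for r in self.block_rates)
        self.aspp_rates = tuple(int(r) for r in self.aspp_rates)
        if len(self.channel_progression) < 2:
            raise ValueError("channel_progression needs at least two stages")
        for a, b in zip(self.channel_progression, self.channel_progression[1:]):
            if b != 2 * a:
                raise ValueError("channel_progression must double at every stage")
        if self.input_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} is not divisible by 2^{self.depth}"
            )
        if self.in_channels not in (1, 3):
            raise ValueError("in_channels must be 1 or 3")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if self.head_activation not in ("auto", "sigmoid", "softmax"):
            raise ValueError("head_activation must be auto, sigmoid or softmax")
        if self.l1_merge not in ("concat", "add"):
            raise ValueError("l1_merge must be concat or add")

    @property
    def depth(self) -> int:
        """Number of pooling stages (and decoder stages)."""
        return len(self.channel_progression) - 1

    @property
    def activation(self) -> str:
        if self.head_activation != "auto":
            return self.head_activation
        return "sigmoid" if self.num_classes == 1 else "softmax"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["attention"] = asdict(self.attention)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        att = d.pop("attention", {})
        if not isinstance(att, AttentionConfig):
            att = AttentionConfig(**att)
        return cls(attention=att, **d)


@dataclass(frozen=True)
class LayerEntry:
    index: int
    tag: str  # encoder | bottleneck | decoder | output
    role: str
    out_shape: tuple[int, int, int]  # (C, H, W)

    @property
    def name(self) -> str:
        return f"L{self.index}"


class LayerRegistry:
    """Ordered macro-layer registry L1..Ln with role tags and shapes."""

    def __init__(self, entries: list[LayerEntry]):
        self.entries = entries
        self._by_index = {e.index: e for e in entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, index: int) -> LayerEntry:
        return self._by_index[index]

    def __iter__(self):
        return iter(self.entries)

    def count(self, tag: str) -> int:
        return sum(1 for e in self.entries if e.tag == tag)

    def to_list(self) -> list[dict]:
        return [
            {"index": e.index, "tag": e.tag, "role": e.role, "out_shape": list(e.out_shape)}
            for e in self.entries
        ]


def decoder_skip_map(cfg: ModelConfig) -> list[tuple[int, int]]:
    """Decoder-stage / encoder-layer couplings as (decoder, encoder) indices.

    Decoder stage i (1-based, deepest first) starts at index
    ``2*depth + 3 + 4*(i-1) + 1`` and consumes the encoder block at index
    ``2*(depth + 1 - i)`` — a stride of +4 on the decoder side and -2 on the
    encoder side.  For the default depth this is exactly
    [(14, 10), (18, 8), (22, 6), (26, 4), (30, 2)].
    """
    D = cfg.depth
    return [(2 * D + 4 + 4 * (i - 1), 2 * (D + 1 - i)) for i in range(1, D + 1)]


class MADRNet(nn.Module):
    """The assembled encoder-decoder segmentation network."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.channel_progression
        D = cfg.depth

        self.conv_in = nn.Conv2d(cfg.in_channels, ch[0], 1, rng=rng)  # L1
        self.enc_blocks = nn.ModuleList()
        prev = ch[0]
        for c in ch:  # six blocks: 32, 64, ..., 1024
            self.enc_blocks.append(
                MultiDilatedResidualBlock(prev, c, cfg.block_rates,
                                          cfg.convs_per_branch, rng=rng)
            )
            prev = c
        self.bottleneck = ASPP(ch[-1], ch[-1], cfg.aspp_rates,
                               cfg.aspp_pool_mode, rng=rng)

        self.up_convs = nn.ModuleList()
        self.attentions = nn.ModuleList()
        self.dec_blocks = nn.ModuleList()
        cur = ch[-1]
        for i in range(1, D + 1):
            skip_c = ch[D - i]  # 512, 256, 128, 64, 32
            self.up_convs.append(nn.ConvTranspose2d(cur, skip_c, rng=rng))
            self.attentions.append(CSAM(skip_c, cfg.attention, rng=rng))
            self.dec_blocks.append(
                MultiDilatedResidualBlock(2 * skip_c, skip_c, cfg.block_rates,
                                          cfg.convs_per_branch, rng=rng)
            )
            cur = skip_c
        head_in = cur + ch[0] if cfg.l1_merge == "concat" else cur
        self.head_aspp = ASPP(head_in, cfg.head_width, cfg.aspp_rates,
                              cfg.aspp_pool_mode, rng=rng)
        self.classifier = nn.Conv2d(cfg.head_width, cfg.num_classes, 1, rng=rng)
        self.registry = self._build_registry()

    # ------------------------------------------------------------- registry
    def _build_registry(self) -> LayerRegistry:
        cfg = self.cfg
        ch = cfg.channel_progression
        D = cfg.depth
        s = cfg.input_size
        entries: list[LayerEntry] = []

        def put(tag, role, c, hw):
            entries.append(LayerEntry(len(entries) + 1, tag, role, (c, hw, hw)))

        put("encoder", "conv-in 1x1", ch[0], s)
        hw = s
        for j, c in enumerate(ch, start=1):
            put("encoder", f"residual-block-{j}", c, hw)
            if j <= D:
                hw //= 2
                put("encoder", f"maxpool-{j}", c, hw)
        put("bottleneck", "aspp-bottleneck", ch[-1], hw)
        for i in range(1, D + 1):
            skip_c = ch[D - i]
            hw *= 2
            put("decoder", f"upsample-{i} (transposed conv)", skip_c, hw)
            put("decoder", f"csam-{i} (on encoder skip)", skip_c, hw)
            put("decoder", f"skip-concat-{i}", 2 * skip_c, hw)
            put("decoder", f"residual-block-dec-{i}", skip_c, hw)
        head_in = ch[0] * 2 if cfg.l1_merge == "concat" else ch[0]
        put("decoder", f"l1-{cfg.l1_merge}", head_in, hw)
        put("decoder", "aspp-head", cfg.head_width, hw)
        put("decoder", "classifier 1x1", cfg.num_classes, hw)
        put("output", cfg.activation, cfg.num_classes, hw)
        return LayerRegistry(entries)

    # -------------------------------------------------------------- forward
    def forward(self, x) -> Tensor:
        x = ag.as_tensor(x)
        cfg = self.cfg
        N, C, H, W = x.shape
        if C != cfg.in_channels:
            raise ValueError(f"expected {cfg.in_channels} input channels, got {C}")
        if H != cfg.input_size or W != cfg.input_size:
            raise ValueError(
                f"expected {cfg.input_size}x{cfg.input_size} input, got {H}x{W}"
            )
        D = cfg.depth
        l1 = self.conv_in(x)
        h = l1
        skips: list[Tensor] = []
        for j, block in enumerate(self.enc_blocks, start=1):
            h = block(h)
            if j <= D:
                skips.append(h)
                h = ag.maxpool2d(h)
        h = self.bottleneck(h)
        for i in range(D):
            h = self.up_convs[i](h)
            gated = self.attentions[i](skips[D - 1 - i])
            h = self.dec_blocks[i](ag.concat([h, gated], axis=1))
        if cfg.l1_merge == "concat":
            h = ag.concat([h, l1], axis=1)
        else:
            h = h + l1
        h = self.head_aspp(h)
        logits = self.classifier(h)
        if cfg.activation == "sigmoid":
            # clip so outputs stay strictly inside (0, 1) even when the
            # single-precision sigmoid saturates on large logits
            return ag.clip(ag.sigmoid(logits), 1e-7, 1.0 - 1e-7)
        return nn.softmax(logits, axis=1)


def build_model(cfg: ModelConfig) -> tuple[MADRNet, LayerRegistry]:
    """Build the network and return it with its layer registry."""
    model = MADRNet(cfg)
    return model, model.registry


def count_trainable_parameters(model: nn.Module) -> int:
    """Exact number of learnable scalars in the model."""
    return int(sum(p.size for p in model.parameters()))
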