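"""Dense-connectivity embedding U-net (DEU) for dual-sequence segmentation.

The network takes one 2D slice per channel (one or two input channels),
encodes each channel through its own first-stage encoder block, fuses them
by channel-wise concatenation, passes the fused low-level features through a
dense connectivity block (DenseNet-style micro-blocks plus a compressing
transition with 2×2 average pooling), continues through further encoder
blocks, and decodes symmetrically with transposed convolutions and skip
concatenations down a sigmoid head.

Spatial bookkeeping: with ``n = len(channels_per_stage)`` encoder stages
there are ``n + 1`` downsamplings (each encoder stage halves once; the
dense transition halves once more) matched by ``n + 1`` decoder doublings,
so the output probability map has exactly the input size.

All widths are configuration-relative; the defaults (stage widths
32/64/128/256, growth rate 32, four dense micro-blocks, 8 normalization
groups, leaky-ReLU slope 0.1) are the reference configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.layers import (
    AvgPool2d,
    Conv2d,
    ConvTranspose2d,
    GroupNorm,
    LeakyReLU,
    group_norm_forward,
    leaky_relu,
    sigmoid,
)

__all__ = [
    "DEUConfig",
    "NetworkHandle",
    "ConfigError",
    "build_deu",
    "build_single_sequence",
    "leaky_relu",
    "group_normalize",
    "dense_block_width",
]


class ConfigError(ValueError):
    """Raised for an invalid architecture configuration, before any allocation."""


def group_normalize(features: np.ndarray, groups: int, epsilon: float = 1e-5) -> np.ndarray:
    """Normalize (C, H, W) features per channel group to zero mean / unit variance."""
    try:
        return group_norm_forward(features, groups, epsilon)
    except ValueError as e:
        raise ConfigError(str(e)) from e


def dense_block_width(in_width: int, growth_rate: int, micro_blocks: int) -> int:
    """Pre-transition channel width of a dense block: in_width + m*K."""
    return in_width + micro_blocks * growth_rate


@dataclass
class DEUConfig:
    """Architectural hyperparameters of DEU and its single-sequence variant."""

    input_size: tuple[int, int] = (256, 256)
    base_channels: int = 32
    channels_per_stage: tuple[int, ...] | None = None
    growth_rate: int = 32
    dense_micro_blocks: int = 4
    gn_groups: int = 8
    lrelu_alpha: float = 0.1
    dual_input: bool = True
    bottleneck_factor: int = 4
    gn_eps: float = 1e-5

    def __post_init__(self) -> None:
        if self.channels_per_stage is None:
            self.channels_per_stage = tuple(self.base_channels * 2**i for i in range(4))
        else:
            self.channels_per_stage = tuple(int(c) for c in self.channels_per_stage)
        self.validate()

    # -- derived widths ----------------------------------------------------
    @property
    def n_stages(self) -> int:
        return len(self.channels_per_stage)

    @property
    def n_downsamplings(self) -> int:
        # each encoder stage halves once; the dense transition halves once more
        return self.n_stages + 1

    @property
    def dense_in_width(self) -> int:
        w0 = self.channels_per_stage[0]
        return 2 * w0 if self.dual_input else w0

    @property
    def dense_out_width(self) -> int:
        # transition compresses back to the dense input width
        return self.dense_in_width

    def validate(self) -> None:
        if not 0 < self.lrelu_alpha < 1:
            raise ConfigError(f"lrelu_alpha must lie in (0, 1), got {self.lrelu_alpha}")
        if self.n_stages < 2:
            raise ConfigError("need at least two encoder stages")
        g = self.gn_groups
        for w in self.channels_per_stage:
            if w % g:
                raise ConfigError(f"stage width {w} not divisible by gn_groups {g}")
        K, m = self.growth_rate, self.dense_micro_blocks
        if K % g or (self.bottleneck_factor * K) % g:
            raise ConfigError(f"growth rate {K} (and bottleneck {self.bottleneck_factor}K) "
                              f"must be divisible by gn_groups {g}")
        for i in range(m):
            if (self.dense_in_width + i * K) % g:
                raise ConfigError(
                    f"dense micro-block input width {self.dense_in_width + i * K} "
                    f"not divisible by gn_groups {g}")
        div = 2 ** self.n_downsamplings
        for s in self.input_size:
            if s % div:
                raise ConfigError(
                    f"input size {s} not divisible by 2^{self.n_downsamplings} = {div}")


# ---------------------------------------------------------------------------
# blocks


class _EncoderBlock:
    """Three 3×3 convolutions; GN + LReLU after the first two; the third at
    stride 2 downsamples.  Exposes the pre-downsampling features for the
    decoder skip connection."""

    def __init__(self, in_w: int, out_w: int, cfg: DEUConfig, rng, dtype):
        g, a = cfg.gn_groups, cfg.lrelu_alpha
        self.conv1 = Conv2d(in_w, out_w, 3, 1, rng=rng, dtype=dtype)
        self.gn1 = GroupNorm(out_w, g, cfg.gn_eps, dtype)
        self.act1 = LeakyReLU(a)
        self.conv2 = Conv2d(out_w, out_w, 3, 1, rng=rng, dtype=dtype)
        self.gn2 = GroupNorm(out_w, g, cfg.gn_eps, dtype)
        self.act2 = LeakyReLU(a)
        self.conv3 = Conv2d(out_w, out_w, 3, 2, rng=rng, dtype=dtype)
        self._layers = [self.conv1, self.gn1, self.act1,
                        self.conv2, self.gn2, self.act2, self.conv3]

    def forward(self, x):
        h = self.act1.forward(self.gn1.forward(self.conv1.forward(x)))
        skip = self.act2.forward(self.gn2.forward(self.conv2.forward(h)))
        down = self.conv3.forward(skip)
        return down, skip

    def backward(self, d_down, d_skip=None):
        g = self.conv3.backward(d_down)
        if d_skip is not None:
            g = g + d_skip
        g = self.conv2.backward(self.gn2.backward(self.act2.backward(g)))
        g = self.conv1.backward(self.gn1.backward(self.act1.backward(g)))
        return g

    def params(self):
        return [p for l in self._layers for p in l.params()]


class _DenseMicroBlock:
    """GN-LReLU-conv(1×1 bottleneck)-GN-LReLU-conv(3×3) emitting K channels."""

    def __init__(self, in_w: int, K: int, cfg: DEUConfig, rng, dtype):
        g, a = cfg.gn_groups, cfg.lrelu_alpha
        bw = cfg.bottleneck_factor * K
        self.gn1 = GroupNorm(in_w, g, cfg.gn_eps, dtype)
        self.act1 = LeakyReLU(a)
        self.conv1 = Conv2d(in_w, bw, 1, 1, rng=rng, dtype=dtype)
        self.gn2 = GroupNorm(bw, g, cfg.gn_eps, dtype)
        self.act2 = LeakyReLU(a)
        self.conv2 = Conv2d(bw, K, 3, 1, rng=rng, dtype=dtype)
        self._layers = [self.gn1, self.act1, self.conv1, self.gn2, self.act2, self.conv2]

    def forward(self, x):
        h = self.conv1.forward(self.act1.forward(self.gn1.forward(x)))
        return self.conv2.forward(self.act2.forward(self.gn2.forward(h)))

    def backward(self, dy):
        g = self.gn2.backward(self.act2.backward(self.conv2.backward(dy)))
        return self.gn1.backward(self.act1.backward(self.conv1.backward(g)))

    def params(self):
        return [p for l in self._layers for p in l.params()]


class _DenseConnectivityBlock:
    """Dense block (every micro-block sees all previous outputs) plus a
    transition: GN → 1×1 compressing convolution → 2×2 average pooling."""

    def __init__(self, in_w: int, out_w: int, cfg: DEUConfig, rng, dtype):
        K, m = cfg.growth_rate, cfg.dense_micro_blocks
        self.in_w, self.K, self.m = in_w, K, m
        self.micro = [
            _DenseMicroBlock(in_w + i * K, K, cfg, rng, dtype) for i in range(m)
        ]
        pre_w = dense_block_width(in_w, K, m)
        self.gn_t = GroupNorm(pre_w, cfg.gn_groups, cfg.gn_eps, dtype)
        self.conv_t = Conv2d(pre_w, out_w, 1, 1, rng=rng, dtype=dtype)
        self.pool = AvgPool2d(2)
        self._widths = None

    def forward(self, x):
        feats = x
        self._widths = [x.shape[0]]
        for mb in self.micro:
            new = mb.forward(feats)
            feats = np.concatenate([feats, new], axis=0)
            self._widths.append(new.shape[0])
        pre = feats  # pre-transition features, in_w + m*K channels
        out = self.pool.forward(self.conv_t.forward(self.gn_t.forward(pre)))
        return out, pre

    def backward(self, d_out, d_pre=None):
        g = self.gn_t.backward(self.conv_t.backward(self.pool.backward(d_out)))
        if d_pre is not None:
            g = g + d_pre
        # walk micro-blocks in reverse, splitting the concat gradient
        for i in range(self.m - 1, -1, -1):
            w_in = self.in_w + i * self.K
            g_in, g_new = g[:w_in], g[w_in:]
            g = g_in + self.micro[i].backward(g_new)
        return g

    def params(self):
        ps = [p for mb in self.micro for p in mb.params()]
        return ps + self.gn_t.params() + self.conv_t.params()


class _DecoderBlock:
    """3×3 transposed convolution (doubles spatial size), concatenation with
    the encoder skip, then two 3×3 conv + GN + LReLU refinements."""

    def __init__(self, in_w: int, skip_w: int, out_w: int, cfg: DEUConfig, rng, dtype):
        g, a = cfg.gn_groups, cfg.lrelu_alpha
        self.skip_w = skip_w
        self.deconv = ConvTranspose2d(in_w, out_w, 3, 2, 1, rng=rng, dtype=dtype)
        self.conv1 = Conv2d(out_w + skip_w, out_w, 3, 1, rng=rng, dtype=dtype)
        self.gn1 = GroupNorm(out_w, g, cfg.gn_eps, dtype)
        self.act1 = LeakyReLU(a)
        self.conv2 = Conv2d(out_w, out_w, 3, 1, rng=rng, dtype=dtype)
        self.gn2 = GroupNorm(out_w, g, cfg.gn_eps, dtype)
        self.act2 = LeakyReLU(a)
        self._layers = [self.deconv, self.conv1, self.gn1, self.act1,
                        self.conv2, self.gn2, self.act2]
        self._up_w = out_w

    def forward(self, x, skip):
        up = self.deconv.forward(x)
        if up.shape[1:] != skip.shape[1:]:
            raise ValueError(
                f"decoder skip shape mismatch: upsampled {up.shape} vs skip {skip.shape}")
        h = np.concatenate([up, skip], axis=0)
        h = self.act1.forward(self.gn1.forward(self.conv1.forward(h)))
        return self.act2.forward(self.gn2.forward(self.conv2.forward(h)))

    def backward(self, dy):
        g = self.conv2.backward(self.gn2.backward(self.act2.backward(dy)))
        g = self.conv1.backward(self.gn1.backward(self.act1.backward(g)))
        d_up, d_skip = g[: self._up_w], g[self._up_w:]
        return self.deconv.backward(d_up), d_skip

    def params(self):
        return [p for l in self._layers for p in l.params()]


# ---------------------------------------------------------------------------
# full network


class DEUNetwork:
    """The assembled network; holds layers, runs forward/backward passes."""

    def __init__(self, cfg: DEUConfig, seed: int = 0, dtype=np.float32):
        cfg.validate()
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        stages = cfg.channels_per_stage
        w0 = stages[0]

        self.in_channels = 2 if cfg.dual_input else 1
        self.stage1 = [
            _EncoderBlock(1, w0, cfg, rng, dtype) for _ in range(self.in_channels)
        ]
        self.dense = _DenseConnectivityBlock(cfg.dense_in_width, cfg.dense_out_width,
                                             cfg, rng, dtype)
        enc_widths = [cfg.dense_out_width] + list(stages[1:])
        self.encoders = [
            _EncoderBlock(enc_widths[i], stages[i + 1], cfg, rng, dtype)
            for i in range(len(stages) - 1)
        ]
        # decoder mirrors: n-1 blocks undo the post-dense encoders, one undoes
        # the transition pooling, one undoes the first-stage downsampling
        dec_specs = []
        in_w = stages[-1]
        for i in range(len(stages) - 1, 0, -1):          # undo encoders[i-1]
            skip_w = stages[i]
            out_w = stages[i - 1] if i > 1 else cfg.dense_out_width
            dec_specs.append((in_w, skip_w, out_w))
            in_w = out_w
        dec_specs.append((in_w, cfg.dense_in_width, w0))  # undo transition pooling
        dec_specs.append((w0, self.in_channels * w0, w0))  # undo stage-1 downsampling
        self.decoders = [
            _DecoderBlock(iw, sw, ow, cfg, rng, dtype) for iw, sw, ow in dec_specs
        ]
        self.head = Conv2d(w0, 1, 1, 1, rng=rng, dtype=dtype)
        self._cache = None

    # -- passes ------------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (C, H, W) with C = 2 (dual) or 1; returns probabilities (H, W)."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 3 or x.shape[0] != self.in_channels:
            raise ValueError(
                f"expected input ({self.in_channels}, H, W), got {x.shape}")
        skips = []
        downs, s1_skips = [], []
        for c, block in enumerate(self.stage1):
            d, s = block.forward(x[c:c + 1])
            downs.append(d)
            s1_skips.append(s)
        fused = np.concatenate(downs, axis=0) if len(downs) > 1 else downs[0]
        s1_skip = np.concatenate(s1_skips, axis=0) if len(s1_skips) > 1 else s1_skips[0]

        h, dense_pre = self.dense.forward(fused)
        enc_skips = []
        for enc in self.encoders:
            h, s = enc.forward(h)
            enc_skips.append(s)

        # deepest first: encoder skips reversed, then the fused pre-dense
        # features, then the stage-1 pre-downsampling features
        skips = list(reversed(enc_skips)) + [fused, s1_skip]
        for dec, s in zip(self.decoders, skips):
            h = dec.forward(h, s)
        logits = self.head.forward(h)[0]
        prob = sigmoid(logits.astype(np.float64))
        self._cache = prob
        return prob

    def backward(self, d_prob: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output probability map."""
        prob = self._cache
        # backward runs in float64 end-to-end (weights stay float32)
        d_logits = np.asarray(d_prob, dtype=np.float64) * prob * (1.0 - prob)
        g = self.head.backward(d_logits[None])
        d_skips = []
        for dec in reversed(self.decoders):
            g, d_s = dec.backward(g)
            d_skips.append(d_s)
        d_skips = list(reversed(d_skips))  # same order as `skips` in forward
        d_enc_skips = list(reversed(d_skips[: len(self.encoders)]))
        d_fused_skip = d_skips[len(self.encoders)]
        d_s1_skip = d_skips[len(self.encoders) + 1]

        for enc, d_s in zip(reversed(self.encoders), reversed(d_enc_skips)):
            g = enc.backward(g, d_s)
        g = self.dense.backward(g)
        d_fused = g + d_fused_skip

        w0 = self.cfg.channels_per_stage[0]
        for c, block in enumerate(self.stage1):
            block.backward(d_fused[c * w0:(c + 1) * w0],
                           d_s1_skip[c * w0:(c + 1) * w0])
        self._cache = None

    # -- bookkeeping -------------------------------------------------------
    def parameters(self):
        ps = [p for b in self.stage1 for p in b.params()]
        ps += self.dense.params()
        ps += [p for b in self.encoders for p in b.params()]
        ps += [p for b in self.decoders for p in b.params()]
        ps += self.head.params()
        return ps

    @property
    def parameter_count(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def get_weights(self):
        return [p.value.copy() for p in self.parameters()]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.parameters(), weights):
            p.value[...] = w


@dataclass
class NetworkHandle:
    """Opaque handle to an instantiated network plus its bookkeeping."""

    network: DEUNetwork
    parameter_count: int
    config: DEUConfig

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.network.forward(x)


def build_deu(cfg: DEUConfig, seed: int = 0) -> NetworkHandle:
    """Build the dual-sequence network (two independent first-stage paths)."""
    if not cfg.dual_input:
        raise ConfigError("build_deu requires dual_input=True; "
                          "use build_single_sequence otherwise")
    net = DEUNetwork(cfg, seed=seed)
    return NetworkHandle(network=net, parameter_count=net.parameter_count, config=cfg)


def build_single_sequence(cfg: DEUConfig, seed: int = 0) -> NetworkHandle:
    """Build the single-sequence ablation variant: one first-stage path whose
    output feeds the dense connectivity block directly; the rest is identical."""
    if cfg.dual_input:
        raise ConfigError("build_single_sequence requires dual_input=False")
    net = DEUNetwork(cfg, seed=seed)
    return NetworkHandle(network=net, parameter_count=net.parameter_count, config=cfg)
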