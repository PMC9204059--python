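"""The three wingbeat classifier architectures.

* **DrosophilaNet** — 8 blocks of (1-D convolution + ReLU, batch norm,
  max-pool window 2), filter counts doubling from 16 to 2,048 with kernel
  size 3, then global average pooling, dropout 0.2 and a linear unit with
  sigmoid output.
* **InceptionFly** — an InceptionTime-style network: 2 residual blocks of
  3 inception modules each. Every module bottlenecks its input to 32
  channels, applies parallel convolutions with kernels 6/12/24 (32 filters
  each) plus a max-pool(3)/1x1-conv branch, concatenates to 128 channels,
  batch-normalizes and applies ReLU. Each block adds a 1x1-projected skip
  connection. Head: global average pooling + linear sigmoid unit.
* **SpectrogramNet** — a pluggable 2-D backbone (default: a small 3-block
  CNN) on the 295x400 dB spectrogram, with the replacement head
  linear(512, ReLU) → dropout(0.2) → linear(1, sigmoid).

Both 1-D families accept either the 5,000-sample waveform or the 1,360-dim
PSD vector; only the input length differs. All models emit one logit per
record; probabilities come from ``Network.predict_proba``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn


@dataclass(frozen=True)
class DrosophilaNetSpec:
    n_blocks: int = 8
    base_filters: int = 16
    kernel_size: int = 3
    pool_window: int = 2
    dropout: float = 0.2

    def filters(self, block: int) -> int:
        """Filter count of 1-based block index: base * 2**(block-1)."""
        return self.base_filters * 2 ** (block - 1)


@dataclass(frozen=True)
class InceptionFlySpec:
    n_residual_blocks: int = 2
    modules_per_block: int = 3
    n_filters: int = 32
    kernel_sizes: tuple[int, ...] = (6, 12, 24)
    bottleneck_channels: int = 32

    @property
    def module_out_channels(self) -> int:
        return (len(self.kernel_sizes) + 1) * self.n_filters


class InceptionModule(nn.Module):
    """Bottleneck + parallel multi-scale convolutions + pooled 1x1 branch."""

    def __init__(self, in_channels: int, spec: InceptionFlySpec,
                 rng: np.random.Generator, dtype=nn.DEFAULT_DTYPE):
        self.bottleneck = nn.Conv1d(in_channels, spec.bottleneck_channels, 1,
                                    rng, dtype=dtype)
        self.branches = [nn.Conv1d(spec.bottleneck_channels, spec.n_filters, k,
                                   rng, dtype=dtype)
                         for k in spec.kernel_sizes]
        self.pool = nn.MaxPoolSame1d(3)
        self.pool_conv = nn.Conv1d(in_channels, spec.n_filters, 1, rng, dtype=dtype)
        self.bn = nn.BatchNorm1d(spec.module_out_channels, dtype=dtype)
        self.relu = nn.ReLU()
        self._splits = [spec.n_filters] * (len(spec.kernel_sizes) + 1)

    def children(self):
        return [self.bottleneck, *self.branches, self.pool, self.pool_conv,
                self.bn, self.relu]

    def forward(self, x, train=False):
        z = self.bottleneck.forward(x, train=train)
        outs = [br.forward(z, train=train) for br in self.branches]
        outs.append(self.pool_conv.forward(self.pool.forward(x, train=train),
                                           train=train))
        y = np.concatenate(outs, axis=1)
        return self.relu.forward(self.bn.forward(y, train=train), train=train)

    def backward(self, grad):
        g = self.bn.backward(self.relu.backward(grad))
        nf = self._splits[0]
        dz = None
        for i, br in enumerate(self.branches):
            d = br.backward(g[:, i * nf:(i + 1) * nf])
            dz = d if dz is None else dz + d
        g_pool = g[:, len(self.branches) * nf:]
        dx_pool = self.pool.backward(self.pool_conv.backward(g_pool))
        return self.bottleneck.backward(dz) + dx_pool


class ResidualBlock(nn.Module):
    """Stack of inception modules with a 1x1-projected additive skip path."""

    def __init__(self, in_channels: int, spec: InceptionFlySpec,
                 rng: np.random.Generator, dtype=nn.DEFAULT_DTYPE):
        out_ch = spec.module_out_channels
        self.modules = []
        ch = in_channels
        for _ in range(spec.modules_per_block):
            self.modules.append(InceptionModule(ch, spec, rng, dtype=dtype))
            ch = out_ch
        self.skip_conv = nn.Conv1d(in_channels, out_ch, 1, rng, dtype=dtype)
        self.skip_bn = nn.BatchNorm1d(out_ch, dtype=dtype)
        self.relu = nn.ReLU()

    def children(self):
        return [*self.modules, self.skip_conv, self.skip_bn, self.relu]

    def forward(self, x, train=False):
        h = x
        for m in self.modules:
            h = m.forward(h, train=train)
        s = self.skip_bn.forward(self.skip_conv.forward(x, train=train),
                                 train=train)
        return self.relu.forward(h + s, train=train)

    def backward(self, grad):
        d = self.relu.backward(grad)
        dh = d
        for m in reversed(self.modules):
            dh = m.backward(dh)
        ds = self.skip_conv.backward(self.skip_bn.backward(d))
        return dh + ds


def build_drosophila_net(spec: DrosophilaNetSpec | None = None,
                         input_length: int = 5000,
                         seed: int = 0,
                         dtype=nn.DEFAULT_DTYPE) -> nn.Network:
    """8-block (by default) 1-D CNN with doubling filter counts."""
    spec = spec or DrosophilaNetSpec()
    if input_length < spec.pool_window ** spec.n_blocks:
        raise ValueError(
            f"input length {input_length} cannot survive {spec.n_blocks} "
            f"halvings")
    rng = np.random.default_rng(seed)
    layers: list[nn.Module] = []
    in_ch = 1
    for block in range(1, spec.n_blocks + 1):
        out_ch = spec.filters(block)
        layers += [nn.Conv1d(in_ch, out_ch, spec.kernel_size, rng, dtype=dtype),
                   nn.ReLU(),
                   nn.BatchNorm1d(out_ch, dtype=dtype),
                   nn.MaxPool1d(spec.pool_window)]
        in_ch = out_ch
    body = nn.Sequential(layers + [nn.GlobalAvgPool1d()])
    head = nn.Sequential([nn.Dropout(spec.dropout, rng),
                          nn.Linear(in_ch, 1, rng, dtype=dtype)])
    return nn.Network(body, head)


def build_inception_fly(spec: InceptionFlySpec | None = None,
                        input_length: int = 5000,
                        seed: int = 0,
                        dtype=nn.DEFAULT_DTYPE) -> nn.Network:
    """InceptionTime-style classifier with 2 residual blocks of 3 modules."""
    spec = spec or InceptionFlySpec()
    if input_length < max(spec.kernel_sizes):
        raise ValueError("input shorter than the largest inception kernel")
    rng = np.random.default_rng(seed)
    blocks: list[nn.Module] = []
    ch = 1
    for _ in range(spec.n_residual_blocks):
        blocks.append(ResidualBlock(ch, spec, rng, dtype=dtype))
        ch = spec.module_out_channels
    body = nn.Sequential(blocks + [nn.GlobalAvgPool1d()])
    head = nn.Linear(ch, 1, rng, dtype=dtype)
    return nn.Network(body, head)


def default_backbone(rng: np.random.Generator, dtype=nn.DEFAULT_DTYPE) -> nn.Module:
    """Small 3-block 2-D CNN ending in global average pooling (32 features)."""
    return nn.Sequential([
        nn.Conv2d(1, 8, 3, rng, dtype=dtype), nn.BatchNorm2d(8, dtype=dtype),
        nn.ReLU(), nn.MaxPool2d(4),
        nn.Conv2d(8, 16, 3, rng, dtype=dtype), nn.BatchNorm2d(16, dtype=dtype),
        nn.ReLU(), nn.MaxPool2d(4),
        nn.Conv2d(16, 32, 3, rng, dtype=dtype), nn.BatchNorm2d(32, dtype=dtype),
        nn.ReLU(), nn.MaxPool2d(2),
        nn.GlobalAvgPool2d(),
    ])


def build_spectrogram_net(backbone: nn.Module | None = None,
                          input_shape: tuple[int, int] = (295, 400),
                          head_width: int = 512,
                          dropout: float = 0.2,
                          seed: int = 0,
                          dtype=nn.DEFAULT_DTYPE) -> nn.Network:
    """Pluggable 2-D backbone with the 512-unit replacement head.

    The backbone must map a (batch, 1, H, W) image to a (batch, features)
    matrix; its feature width is inferred with a dry run so any backbone
    (e.g. a DenseNet-style model) can be plugged in.
    """
    rng = np.random.default_rng(seed)
    backbone = backbone if backbone is not None else default_backbone(rng, dtype=dtype)
    probe = np.zeros((1, 1, *input_shape), dtype=dtype)
    feats = backbone.forward(probe, train=False)
    if feats.ndim != 2:
        raise ValueError("backbone must emit a (batch, features) matrix")
    head = nn.Sequential([
        nn.Linear(feats.shape[1], head_width, rng, dtype=dtype),
        nn.ReLU(),
        nn.Dropout(dropout, rng),
        nn.Linear(head_width, 1, rng, dtype=dtype),
    ])
    return nn.Network(backbone, head)
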