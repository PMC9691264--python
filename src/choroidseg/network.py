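"""Boundary Enhancement Module (BEM) and the boundary-enhanced U-Net.

The BEM refines the feature maps ``f`` of an encoder/decoder block with
three parallel branches:

* **FEB** (feature extraction branch): five parallel convolutions — 1x1 and
  3x3 at dilation rates 1, 2, 4, 6 — concatenated and projected by a 1x1
  convolution + logistic to a single-channel boundary point map ``M``.
* **CEB** (channel enhancement branch): global average pooling, a kernel-3
  convolution across the channel axis, and a logistic, giving per-channel
  weights ``N``.
* **BAB** (boundary activation branch): 1x1 convolution to one channel,
  logistic, then the boundary activation ``Q(x) = exp(-(x-0.5)^2) + 1 -
  exp(-1/4)``, which peaks at 2 - e^{-1/4} for x = 0.5 (boundary-like
  responses) and falls to exactly 1 at x in {0, 1} (interior/background).

The fused output is ``v = f + f * M * Q * N`` (``M``/``Q`` broadcast over
channels, ``N`` over space).  A BEM sits after every encoder and decoder
convolution block of a U-Net backbone; the network also exposes each FEB map
``M^i`` so they can be regressed onto downsampled ground-truth soft point
maps during training.  Each branch can be disabled independently (the
corresponding factor is dropped from the product) for ablation studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    Tensor, Module, Conv2d, BatchNorm2d, ChannelConv1d, concat,
    maxpool2x2, upsample2x2,
)

__all__ = [
    "BEMConfig",
    "bab_activation",
    "FeatureExtractionBranch",
    "ChannelEnhancementBranch",
    "BoundaryActivationBranch",
    "BoundaryEnhancementModule",
    "bem_fuse",
    "ChoroidSegNet",
    "build_segmentation_network",
]

_BAB_OFFSET = 1.0 - float(np.exp(-0.25))


@dataclass(frozen=True)
class BEMConfig:
    """Hyperparameters of the BEM and its placement in the backbone.

    ``dilation_rates`` are the 3x3 branch rates (a 1x1 dilation-1 branch is
    always included alongside them); ``layers_with_bem`` lists block names
    (``enc0..enc{d-1}``, ``dec0..dec{d-1}``), or None for all.
    """

    dilation_rates: tuple[int, ...] = (1, 2, 4, 6)
    ceb_kernel: int = 3
    layers_with_bem: tuple[str, ...] | None = None
    use_feb: bool = True
    use_ceb: bool = True
    use_bab: bool = True

    def __post_init__(self):
        if any(d < 1 for d in self.dilation_rates):
            raise ValueError("dilation rates must be positive integers")
        if self.ceb_kernel % 2 == 0:
            raise ValueError("ceb_kernel must be odd")

    @property
    def any_branch(self) -> bool:
        return self.use_feb or self.use_ceb or self.use_bab


def bab_activation(x):
    """Boundary activation: ``exp(-(x-0.5)^2) + 1 - exp(-1/4)``.

    Symmetric about x = 0.5 where it peaks at 2 - e^{-1/4} (~1.2212);
    equals exactly 1 at x = 0 and x = 1.  Accepts scalars, ndarrays or
    autodiff tensors.
    """
    if isinstance(x, Tensor):
        return (-((x - 0.5) ** 2)).exp() + _BAB_OFFSET
    x = np.asarray(x, dtype=float)
    out = np.exp(-((x - 0.5) ** 2)) + _BAB_OFFSET
    return float(out) if out.ndim == 0 else out


class FeatureExtractionBranch(Module):
    """FEB: parallel dilated convolutions -> concat -> 1x1 conv -> logistic."""

    def __init__(self, cin: int, cfg: BEMConfig, rng: np.random.Generator):
        per_branch = max(4, cin // 4)
        self.branches = [Conv2d(cin, per_branch, 1, rng=rng)]
        self.branches += [
            Conv2d(cin, per_branch, 3, dilation=d, rng=rng)
            for d in cfg.dilation_rates
        ]
        self.project = Conv2d(per_branch * len(self.branches), 1, 1, rng=rng)

    def forward(self, f: Tensor) -> Tensor:
        cat = concat([b(f) for b in self.branches], axis=1)
        return self.project(cat).sigmoid()


class ChannelEnhancementBranch(Module):
    """CEB: global average pooling -> channel conv (k=3) -> logistic."""

    def __init__(self, rng: np.random.Generator):
        self.conv = ChannelConv1d(rng=rng)

    def forward(self, f: Tensor) -> Tensor:
        pooled = f.mean(axis=(2, 3))  # (N, C)
        return self.conv(pooled).sigmoid()


class BoundaryActivationBranch(Module):
    """BAB: 1x1 conv to one channel -> logistic -> boundary activation."""

    def __init__(self, cin: int, rng: np.random.Generator):
        self.conv = Conv2d(cin, 1, 1, rng=rng)

    def forward(self, f: Tensor) -> Tensor:
        return bab_activation(self.conv(f).sigmoid())


def bem_fuse(f: Tensor, M=None, Q=None, N=None) -> Tensor:
    """Fusion ``v = f + f * M * Q * N`` with ``M``/``Q`` (N,1,H,W) broadcast
    over channels and ``N`` (batch, C) broadcast over space.  Disabled
    branches pass None and are omitted from the product."""
    f = f if isinstance(f, Tensor) else Tensor(f)
    boost = f
    for factor in (M, Q):
        if factor is not None:
            factor = factor if isinstance(factor, Tensor) else Tensor(factor)
            if factor.shape[-2:] != f.shape[-2:]:
                raise ValueError("spatial shape mismatch in BEM fusion")
            boost = boost * factor
    if N is not None:
        N = N if isinstance(N, Tensor) else Tensor(N)
        if N.shape[-1] != f.shape[1]:
            raise ValueError("channel weight length must equal channel count")
        boost = boost * N.reshape(N.shape[0], N.shape[-1], 1, 1)
    return f + boost


class BoundaryEnhancementModule(Module):
    def __init__(self, cin: int, cfg: BEMConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.feb = FeatureExtractionBranch(cin, cfg, rng) if cfg.use_feb else None
        self.ceb = ChannelEnhancementBranch(rng) if cfg.use_ceb else None
        self.bab = BoundaryActivationBranch(cin, rng) if cfg.use_bab else None

    def forward(self, f: Tensor) -> tuple[Tensor, Tensor | None]:
        """Returns the fused features ``v`` and the FEB map ``M`` (or None)."""
        M = self.feb(f) if self.feb is not None else None
        N = self.ceb(f) if self.ceb is not None else None
        Q = self.bab(f) if self.bab is not None else None
        if M is None and N is None and Q is None:
            return f, None
        return bem_fuse(f, M, Q, N), M


class _DoubleConv(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.c1 = Conv2d(cin, cout, 3, rng=rng)
        self.b1 = BatchNorm2d(cout)
        self.c2 = Conv2d(cout, cout, 3, rng=rng)
        self.b2 = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return self.b2(self.c2(self.b1(self.c1(x)).relu())).relu()


class ChoroidSegNet(Module):
    """U-Net encoder-decoder with a BEM after every encoder/decoder block.

    ``depth`` resolution halvings around a plain double-conv bottleneck;
    encoder channels ``base * 2^i``.  The forward pass returns the sigmoid
    probability map at input resolution together with the FEB point maps
    ``M^i`` and their downsampling factors relative to the input.
    """

    def __init__(self, depth: int = 4, base_channels: int = 32,
                 bem: BEMConfig | None = None, in_channels: int = 1,
                 seed: int = 0):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.bem_cfg = bem if bem is not None else BEMConfig()
        chans = [base_channels * 2**i for i in range(depth)]
        names = [f"enc{i}" for i in range(depth)] + [f"dec{i}" for i in range(depth)]
        with_bem = (set(self.bem_cfg.layers_with_bem)
                    if self.bem_cfg.layers_with_bem is not None else set(names))

        self.enc = []
        self.enc_bem = []
        cin = in_channels
        for i in range(depth):
            self.enc.append(_DoubleConv(cin, chans[i], rng))
            self.enc_bem.append(
                BoundaryEnhancementModule(chans[i], self.bem_cfg, rng)
                if (f"enc{i}" in with_bem and self.bem_cfg.any_branch) else None
            )
            cin = chans[i]
        self.bottleneck = _DoubleConv(chans[-1], chans[-1] * 2, rng)

        self.dec = []
        self.dec_bem = []
        up_ch = chans[-1] * 2
        for i in reversed(range(depth)):
            self.dec.append(_DoubleConv(up_ch + chans[i], chans[i], rng))
            self.dec_bem.append(
                BoundaryEnhancementModule(chans[i], self.bem_cfg, rng)
                if (f"dec{i}" in with_bem and self.bem_cfg.any_branch) else None
            )
            up_ch = chans[i]
        self.head = Conv2d(chans[0], 1, 1, rng=rng)

    @property
    def n_bem(self) -> int:
        return sum(m is not None and m.feb is not None
                   for m in self.enc_bem + self.dec_bem)

    def forward(self, x: Tensor) -> tuple[Tensor, list[tuple[Tensor, int]]]:
        x = x if isinstance(x, Tensor) else Tensor(x)
        h, w = x.shape[-2:]
        div = 2**self.depth
        if h % div or w % div:
            raise ValueError(
                f"input spatial size {h}x{w} must be divisible by "
                f"2**depth = {div} for {self.depth} pooling stages"
            )
        skips = []
        maps: list[tuple[Tensor, int]] = []
        for i in range(self.depth):
            x = self.enc[i](x)
            if self.enc_bem[i] is not None:
                x, M = self.enc_bem[i](x)
                if M is not None:
                    maps.append((M, 2**i))
            skips.append(x)
            x = maxpool2x2(x)
        x = self.bottleneck(x)
        for j, i in enumerate(reversed(range(self.depth))):
            x = upsample2x2(x)
            x = self.dec[j](concat([skips[i], x], axis=1))
            if self.dec_bem[j] is not None:
                x, M = self.dec_bem[j](x)
                if M is not None:
                    maps.append((M, 2**i))
        return self.head(x).sigmoid(), maps


def build_segmentation_network(
    cfg: BEMConfig | None = None, depth: int = 4, base_channels: int = 32,
    seed: int = 0,
) -> ChoroidSegNet:
    """Construct the boundary-enhanced segmentation network."""
    return ChoroidSegNet(depth=depth, base_channels=base_channels, bem=cfg,
                         seed=seed)


# functional aliases matching the branch names
def feb_forward(f, cin: int | None = None, cfg: BEMConfig | None = None,
                seed: int = 0) -> Tensor:
    """Run a freshly initialised FEB on feature maps ``f`` (N, C, H, W)."""
    f = f if isinstance(f, Tensor) else Tensor(f)
    branch = FeatureExtractionBranch(f.shape[1], cfg or BEMConfig(),
                                     np.random.default_rng(seed))
    return branch(f)


def ceb_forward(f, seed: int = 0) -> Tensor:
    f = f if isinstance(f, Tensor) else Tensor(f)
    return ChannelEnhancementBranch(np.random.default_rng(seed))(f)


def bab_forward(f, seed: int = 0) -> Tensor:
    f = f if isinstance(f, Tensor) else Tensor(f)
    return BoundaryActivationBranch(f.shape[1], np.random.default_rng(seed))(f)
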