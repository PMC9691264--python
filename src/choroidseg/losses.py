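"""Training objective: segmentation BCE, per-layer point-map MSE, a guided
feature (perceptual) loss through a frozen feature extractor, and their
combination.

The total objective is

    L_total = lambda_seg * L_seg + lambda_bp * L_bp,
    L_bp    = L_gf + sum_i L_map^i,

with ``L_seg`` the pixel-mean binary cross entropy between ground-truth and
predicted choroid maps, ``L_map^i`` the mean squared error between the FEB
point map of the i-th BEM and the ground-truth soft point map max-pooled to
that layer's resolution, and ``L_gf`` a feature-space L1 distance: the
ground-truth map and the predicted map are each concatenated with the
ground-truth soft point map, passed through a frozen convolutional feature
hierarchy, and compared layer by layer, each layer normalized by its element
count.

The reference formulation uses an ImageNet-pretrained VGG-19 as the frozen
extractor.  Pretrained weights are an external asset: when a weights path is
configured but absent, an explicit error names it.  By default a small
deterministic randomly-initialised frozen extractor is used — the guidance
contract (zero at identity, nonnegative, frozen) is weight-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import Tensor, Module, concat, conv2d, maxpool2x2

__all__ = [
    "LossWeights",
    "PerceptualConfig",
    "FrozenExtractor",
    "segmentation_loss",
    "point_map_loss",
    "guided_feature_loss",
    "boundary_perceptual_loss",
    "total_loss",
]

_EPS = 1e-7
# standard channel normalization of ImageNet-pretrained hierarchies
_NORM_MEAN = np.array([0.485, 0.456, 0.406], np.float32).reshape(1, 3, 1, 1)
_NORM_STD = np.array([0.229, 0.224, 0.225], np.float32).reshape(1, 3, 1, 1)


@dataclass(frozen=True)
class LossWeights:
    lambda_seg: float = 0.5
    lambda_bp: float = 0.5

    def __post_init__(self):
        if self.lambda_seg < 0 or self.lambda_bp < 0:
            raise ValueError("loss weights must be >= 0")


def _maybe_scalar(out: Tensor, *inputs):
    if any(isinstance(x, Tensor) for x in inputs):
        return out
    return float(out.data)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, np.float32))


def segmentation_loss(s_gt, s_pred, reduction: str = "mean"):
    """Binary cross entropy between ground truth and predicted probability
    maps; predictions are clamped to [eps, 1-eps].  ``reduction`` is
    ``"mean"`` (pixel mean, the default, keeping the loss scale independent
    of image size) or ``"sum"``."""
    gt, pred = _as_tensor(s_gt), _as_tensor(s_pred)
    if gt.shape != pred.shape:
        raise ValueError("shape mismatch between ground truth and prediction")
    p = pred.clip(_EPS, 1.0 - _EPS)
    ll = gt * p.log() + (1.0 - gt) * (1.0 - p).log()
    out = -(ll.mean() if reduction == "mean" else ll.sum())
    return _maybe_scalar(out, s_gt, s_pred)


def point_map_loss(m_pred, m_gt):
    """Mean squared error between a predicted FEB point map and its
    ground-truth soft point map at the same resolution."""
    pred, gt = _as_tensor(m_pred), _as_tensor(m_gt)
    if pred.shape != gt.shape:
        raise ValueError("point map shape mismatch")
    out = ((pred - gt) ** 2).mean()
    return _maybe_scalar(out, m_pred, m_gt)


class FrozenExtractor(Module):
    """A frozen convolutional feature hierarchy with pooled stages.

    Layout follows the VGG pattern (two 3x3 conv+relu per stage, 2x2 max
    pooling between stages, taps at the first four pooled outputs), scaled
    to a width suitable for CPU use.  Weights are drawn once from a seeded
    generator and are never trained; gradients still flow to the *input*,
    which is what perceptual supervision needs.
    """

    def __init__(self, channels=(8, 16, 16, 16), seed: int = 12345):
        rng = np.random.default_rng(seed)
        self.stages = []
        cin = 3
        for c in channels:
            ws = []
            for _ in range(2):
                std = float(np.sqrt(2.0 / (cin * 9)))
                ws.append(Tensor(rng.normal(0.0, std, (c, cin, 3, 3))))
                cin = c
            self.stages.append(ws)
        self.training = False

    def features(self, x: Tensor) -> list[Tensor]:
        taps = []
        for ws in self.stages:
            for w in ws:
                x = conv2d(x, w).relu()
            x = maxpool2x2(x)
            taps.append(x)
        return taps


@dataclass
class PerceptualConfig:
    """Configuration of the guided feature loss extractor.

    ``weights_path`` may point to a ``.npz`` of pretrained extractor weights;
    if set but missing, an explicit error names the asset.  When unset, a
    deterministic randomly-initialised frozen extractor is used.
    """

    extractor: FrozenExtractor | None = None
    weights_path: str | None = None
    normalize: bool = True

    def resolve(self) -> FrozenExtractor:
        if self.extractor is not None:
            return self.extractor
        if self.weights_path is not None:
            p = Path(self.weights_path)
            if not p.exists():
                raise FileNotFoundError(
                    f"pretrained extractor weights not found: {p} — provide "
                    "the weights file or leave weights_path unset to use the "
                    "built-in frozen random extractor"
                )
            data = np.load(p)
            ext = FrozenExtractor()
            flat = [w for ws in ext.stages for w in ws]
            for i, w in enumerate(flat):
                w.data = np.asarray(data[f"w{i}"], np.float32)
            self.extractor = ext
            return ext
        self.extractor = FrozenExtractor()
        return self.extractor


def _lift_to_rgb(seg, pmap, normalize: bool) -> Tensor:
    """Concatenate (segmentation map, soft point map) and lift the 2-channel
    stack to the extractor's 3-channel input: third channel zeros, then
    standard channel normalization."""
    seg, pmap = _as_tensor(seg), _as_tensor(pmap)
    if seg.ndim == 2:
        seg = seg.reshape(1, 1, *seg.shape)
    if pmap.ndim == 2:
        pmap = pmap.reshape(1, 1, *pmap.shape)
    zeros = Tensor(np.zeros_like(seg.data))
    x = concat([seg, pmap, zeros], axis=1)
    if normalize:
        x = (x - Tensor(_NORM_MEAN)) / Tensor(_NORM_STD)
    return x


def guided_feature_loss(s_gt, s_pred, m_gt, pc: PerceptualConfig | None = None):
    """Feature-space L1 distance between the (GT, point-map) and
    (prediction, point-map) stacks, summed over tapped layers and normalized
    by each layer's element count."""
    pc = pc or PerceptualConfig()
    ext = pc.resolve()
    x_gt = _lift_to_rgb(_as_tensor(s_gt).detach(), _as_tensor(m_gt).detach(),
                        pc.normalize)
    x_pred = _lift_to_rgb(s_pred, _as_tensor(m_gt).detach(), pc.normalize)
    feats_gt = ext.features(x_gt)
    feats_pred = ext.features(x_pred)
    out = None
    for fg, fp in zip(feats_gt, feats_pred):
        n_i = float(np.prod(fg.shape))
        term = (fp - fg.detach()).abs().sum() * (1.0 / n_i)
        out = term if out is None else out + term
    return _maybe_scalar(out, s_pred)


def boundary_perceptual_loss(gf, map_losses):
    """BP-loss: guided feature loss plus the sum of per-BEM point-map
    losses (one entry per active BEM layer)."""
    out = _as_tensor(gf) if isinstance(gf, Tensor) else gf
    for ml in map_losses:
        out = out + ml
    return out


def total_loss(seg, bp, w: LossWeights | None = None):
    """Weighted joint objective ``lambda_seg * seg + lambda_bp * bp``."""
    w = w or LossWeights()
    return w.lambda_seg * seg + w.lambda_bp * bp
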