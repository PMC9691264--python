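"""Training and inference for the boundary-enhanced segmentation network.

The optimizer follows the reference protocol (Adam, initial learning rate
5e-4, batch size 8); the number of steps/epochs is scaled to the problem at
hand.  Each step minimises

    0.5 * BCE(seg) + 0.5 * (guided-feature loss + sum of point-map MSEs)

where the point-map targets are the ground-truth soft point maps max-pooled
to each BEM layer's resolution, and the BP term can be disabled for
ablation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, Adam
from .network import ChoroidSegNet, BEMConfig
from .losses import (
    LossWeights, PerceptualConfig, segmentation_loss, point_map_loss,
    guided_feature_loss, boundary_perceptual_loss, total_loss,
)
from .pointmap import select_boundary_points, render_soft_point_map, \
    downsample_point_map, SoftPointMap
from .synthetic import SimConfig, sample_boundary_curve, render_bscan
from .trace import BoundaryTrace

__all__ = ["TrainSettings", "SegmentationDataset", "make_bscan_dataset",
           "train_model", "predict"]


@dataclass
class TrainSettings:
    steps: int = 200
    batch_size: int = 8
    lr: float = 5e-4
    k_points: int = 10
    sigma: float = 5.0
    use_bp_loss: bool = True
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0


@dataclass
class SegmentationDataset:
    """In-memory training set: images (n,1,H,W) in [0,1], masks (n,1,H,W),
    ground-truth traces and full-resolution soft point maps."""

    images: np.ndarray
    masks: np.ndarray
    traces: list[BoundaryTrace]
    point_maps: list[SoftPointMap]

    def __len__(self) -> int:
        return self.images.shape[0]


def make_bscan_dataset(config: SimConfig, n: int, seed: int,
                       k_points: int = 10, sigma: float = 5.0
                       ) -> SegmentationDataset:
    """Render ``n`` independent synthetic B-scans with ground truth and
    soft point maps (merged BM + CSI points)."""
    rng = np.random.default_rng(seed)
    h, w = config.height, config.width
    mean_bm = config.bm_mean_row_frac * h
    thick_px = config.mean_choroid_thickness / config.axial_spacing
    var_px = config.thickness_variation / config.axial_spacing
    images = np.empty((n, 1, h, w), np.float32)
    masks = np.empty((n, 1, h, w), np.float32)
    traces, pmaps = [], []
    for i in range(n):
        s1, s2 = rng.integers(0, 2**31, size=2)
        bm = sample_boundary_curve(w, mean_bm, config.boundary_smoothness,
                                   config.boundary_amplitude, int(s1), height=h)
        dthick = sample_boundary_curve(w, thick_px, config.boundary_smoothness,
                                       var_px, int(s2)) if var_px > 0 else thick_px
        csi = np.clip(bm + dthick, None, h - 1e-6)
        img, msk, tr = render_bscan(bm, csi, config,
                                    np.random.default_rng(int(rng.integers(0, 2**31))))
        images[i, 0] = img.astype(np.float32) / config.max_intensity
        masks[i, 0] = msk
        traces.append(tr)
        pts = select_boundary_points(tr, k_points)
        pmaps.append(render_soft_point_map(pts, (h, w), sigma))
    return SegmentationDataset(images, masks, traces, pmaps)


def _map_targets(pmaps: list[SoftPointMap], factors: list[int]
                 ) -> dict[int, np.ndarray]:
    """Stack per-image GT point maps max-pooled to each required factor."""
    out = {}
    for f in sorted(set(factors)):
        out[f] = np.stack([downsample_point_map(pm, f).values for pm in pmaps])
    return out


def train_model(net: ChoroidSegNet, data: SegmentationDataset,
                settings: TrainSettings | None = None,
                val: SegmentationDataset | None = None) -> dict:
    """Train in place; returns a history dict with per-step losses."""
    st = settings or TrainSettings()
    rng = np.random.default_rng(st.seed)
    opt = Adam(net.parameters(), lr=st.lr)
    pc = PerceptualConfig() if st.use_bp_loss else None

    # probe BEM factors once to precompute pooled point-map targets
    net.eval()
    _, probe_maps = net(data.images[:1])
    factors = [f for _, f in probe_maps]
    targets = _map_targets(data.point_maps, factors) if (
        st.use_bp_loss and factors) else {}
    full_maps = np.stack([pm.values for pm in data.point_maps])

    history = {"step": [], "loss": [], "seg": [], "bp": []}
    net.train()
    for step in range(st.steps):
        idx = rng.choice(len(data), size=min(st.batch_size, len(data)),
                         replace=False)
        x = Tensor(data.images[idx])
        gt = data.masks[idx]
        pred, maps = net(x)
        seg = segmentation_loss(Tensor(gt), pred)
        if st.use_bp_loss:
            map_losses = [point_map_loss(M, Tensor(targets[f][idx, None]))
                          for M, f in maps]
            gf = guided_feature_loss(gt, pred, full_maps[idx, None], pc)
            bp = boundary_perceptual_loss(gf, map_losses)
        else:
            bp = Tensor(0.0)
        loss = total_loss(seg, bp, st.weights)
        opt.zero_grad()
        loss.backward()
        opt.step()
        history["step"].append(step)
        history["loss"].append(loss.item())
        history["seg"].append(seg.item())
        history["bp"].append(bp.item())
    net.eval()
    return history


def predict(net: ChoroidSegNet, images: np.ndarray, batch_size: int = 8,
            threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Run inference; returns (probability maps, binary masks)."""
    net.eval()
    probs = []
    for i in range(0, len(images), batch_size):
        p, _ = net(images[i:i + batch_size])
        probs.append(p.data)
    probs = np.concatenate(probs, axis=0)
    return probs, (probs >= threshold).astype(np.uint8)
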