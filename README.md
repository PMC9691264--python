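# choroidseg

Boundary-enhanced choroid segmentation and morphometry for retinal OCT.

The choroid — the vascular layer between retina and sclera — thins and
reshapes in high myopia and other eye diseases, making its thickness a
routine OCT biomarker.  Its upper boundary (Bruch's membrane, BM) is sharp,
but the choroidal–scleral interface (CSI) is faint, and generic
segmentation networks localise it poorly.  This package implements a
segmentation network whose encoder/decoder blocks each carry a Boundary
Enhancement Module (BEM) refining block features `f` as

    v = f + f · M · Q · N

where `M` is a boundary point map from parallel dilated convolutions
(1×1, and 3×3 at dilation 1/2/4/6 → concat → 1×1 conv → sigmoid), `N` a
channel weighting vector (global average pooling → kernel-3 channel
convolution → sigmoid), and `Q` a spatial activation map: a 1×1 conv +
sigmoid followed by

    Q(x) = exp(−(x−0.5)²) + 1 − e^{−1/4},

which peaks at `2 − e^{−1/4} ≈ 1.2212` for boundary-like responses
(x ≈ 0.5) and is exactly 1 at saturated interior/background responses.
Training jointly minimises

    L = 0.5·BCE(S, Ŝ) + 0.5·( L_GF + Σ_i MSE(M^i, M_GT^i) ),

supervising each BEM's point map against a Gaussian *soft point map* —
`S_{ij} = max_k exp(−((i−x_k)² + (j−y_k)²)/(2σ²))` over key points selected
on the BM/CSI boundaries — plus a perceptual (feature-space L1) term
through a frozen extractor.  Evaluation covers region metrics
(Dice/IoU/Acc/Sen), per-boundary Average Unsigned Surface Detection Error
(AUSDE) and thickness difference (TD), and downstream morphometry: en-face
thickness maps, ETDRS 1/3/6 mm subfield statistics, and 3-D point-cloud
volume, surface area and curvature with Welch group comparisons.

Real choroid-annotated OCT datasets are essentially all private, so the
package ships a synthetic OCT generator (three-band B-scans, smooth
boundary fields, multiplicative gamma speckle, tunable CSI contrast and bit
depth) that provides exact ground truth for every stage.  The network runs
on a small built-in numpy autodiff engine (`choroidseg.nn`) — no GPU
framework required — and trains at desk scale in minutes on one CPU core.

## Worked example

```python
import numpy as np
from choroidseg import (SimConfig, generate_volume, extract_boundaries,
                        ausde, thickness_map, etdrs_subfields, bab_activation)

print(f"Q(0.5) = {bab_activation(0.5):.6f}, Q(0) = {bab_activation(0.0):.1f}")

cfg = SimConfig(width=128, height=128, n_bscans=40, axial_spacing=8.0,
                lateral_spacing=47.0, slice_spacing=75.0,
                mean_choroid_thickness=230.0, csi_contrast=0.6,
                speckle_shape=8.0, seed=11, bm_mean_row_frac=0.3,
                boundary_amplitude=6.0, boundary_smoothness=48.0,
                thickness_variation=40.0)
volume, masks, traces = generate_volume(cfg)

rec = [extract_boundaries(m) for m in masks]
err_bm = np.mean([ausde(r.bm_rows, t.bm_rows) for r, t in zip(rec, traces)])
print(f"mask->trace AUSDE(BM) = {err_bm:.3f} px")

tmap = thickness_map(rec, cfg.axial_spacing, cfg.lateral_spacing,
                     cfg.slice_spacing)
rep = etdrs_subfields(tmap)
print(f"ETDRS global average = {rep.global_average:.1f} um "
      f"(configured mean {cfg.mean_choroid_thickness:.0f} um)")
```

prints

```
Q(0.5) = 1.221199, Q(0) = 1.0
mask->trace AUSDE(BM) = 0.498 px
ETDRS global average = 232.6 um (configured mean 230 um)
```

`Q(0.5)` is the peak boundary weight of the activation branch; the
sub-pixel AUSDE shows mask→boundary extraction is consistent with the
generator's rounding convention; and the ETDRS average recovers the
configured thickness to well within one axial pixel (8 µm).

Training end to end on synthetic scans (the desk-scale study used by the
test suite — ~5 minutes on one CPU core):

```python
from choroidseg.experiments import run_desk_experiment
r = run_desk_experiment(seed=1, steps=200, n_train=200, n_val=50)
print(r["dice"], r["ausde_bm"], r["ausde_csi"])
```

## Command line

A single `choroidseg` entry point chains the pipeline:

```bash
choroidseg simulate   --config cfg.yaml --out data/
choroidseg pointmap   --traces data/traces --k 10 --sigma 5 --shape 256 512 --out pmaps/
choroidseg train      --config cfg.yaml --data data/ --out run/
choroidseg predict    --checkpoint run/checkpoint.pkl --images data/ --out preds/
choroidseg evaluate   --pred preds/ --gt data/masks --out report.csv
choroidseg morphometry --traces data/traces --meta data/meta.json --out morph/
choroidseg crossval   --n-items 640 --k 4 --seed 0 --out folds.json
```

Exit codes: 0 ok, 2 configuration error, 3 data error.  Every run writes
its resolved configuration and seed next to its outputs.

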