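"""Synthetic OCT B-scan and volume generator with known choroid boundaries.

Real choroid-annotated OCT volumes are scarce and mostly private, so this
module renders three-band B-scans (retina / choroid / sclera) with smooth BM
and CSI boundary curves, multiplicative gamma speckle, a deliberately
weakened choroid–sclera intensity step, and configurable bit depth.  Every
render returns its own exact ground truth (binary mask + boundary trace), so
segmentation, metrics and morphometry can be tested end to end without any
download.

Conventions
-----------
Row index 0 is the top of the B-scan; depth increases with row.  Boundary
curves are real-valued.  The choroid mask is 1 exactly for pixel rows ``r``
with ``ceil(bm) <= r < ceil(csi)`` (half-open rounding).

Band intensities before speckle/quantization are fixed on a [0, 1] scale:
retina 0.8, choroid 0.5, sclera ``0.5 - 0.3 * csi_contrast`` — so
``csi_contrast = 0`` makes the CSI genuinely invisible, and 1 gives a crisp
0.3 step.  Speckle is multiplicative gamma noise with unit mean (shape ``k``,
scale ``1/k``), which leaves band means unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from .trace import BoundaryTrace

__all__ = [
    "SimConfig",
    "sample_boundary_curve",
    "render_bscan",
    "generate_volume",
    "write_dataset",
]

_ALLOWED_BIT_DEPTHS = (6, 8, 10, 12, 16)

# band intensities on [0, 1] before speckle / quantization
_RETINA_LEVEL = 0.8
_CHOROID_LEVEL = 0.5
_CSI_STEP = 0.3


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic acquisition.

    Defaults emulate a macular SD-OCT raster: a 512-column B-scan covering
    ~3 mm laterally at ~4 µm axial sampling, mean choroidal thickness 230 µm
    (a typical healthy macular value), smooth boundary undulation, moderate
    speckle and 8-bit quantization.

    Parameters
    ----------
    axial_spacing, lateral_spacing : float
        Pixel size in µm/px along depth (rows) and width (columns).
    slice_spacing : float
        Distance between adjacent B-scans in µm.
    mean_choroid_thickness : float
        Target mean BM→CSI distance in µm.
    boundary_smoothness : float
        Correlation length of boundary undulation in pixels (shortest
        sinusoid wavelength used); larger = smoother curves.
    csi_contrast : float
        Choroid/sclera step strength in [0, 1]; 0 hides the CSI entirely.
    speckle_shape : float
        Gamma shape parameter of the multiplicative speckle (unit mean);
        ``inf`` or <= 0 disables speckle.
    bm_mean_row_frac : float
        Mean BM row as a fraction of image height.
    boundary_amplitude : float
        Maximum BM deviation from its mean row, in pixels.
    thickness_variation : float
        Maximum smooth choroid-thickness modulation in µm (0 = constant
        thickness everywhere).
    """

    width: int = 512
    height: int = 256
    n_bscans: int = 32
    axial_spacing: float = 4.0
    lateral_spacing: float = 6.0
    slice_spacing: float = 24.0
    mean_choroid_thickness: float = 230.0
    boundary_smoothness: float = 96.0
    csi_contrast: float = 0.5
    speckle_shape: float = 8.0
    bit_depth: int = 8
    seed: int = 0
    bm_mean_row_frac: float = 0.35
    boundary_amplitude: float = 8.0
    thickness_variation: float = 40.0

    def __post_init__(self) -> None:
        if min(self.axial_spacing, self.lateral_spacing, self.slice_spacing) <= 0:
            raise ValueError("all spacings must be > 0")
        if not 0.0 <= self.csi_contrast <= 1.0:
            raise ValueError("csi_contrast must lie in [0, 1]")
        if self.bit_depth not in _ALLOWED_BIT_DEPTHS:
            raise ValueError(f"bit_depth must be one of {_ALLOWED_BIT_DEPTHS}")
        if self.width < 2 or self.height < 2 or self.n_bscans < 1:
            raise ValueError("width/height must be >= 2 and n_bscans >= 1")
        if self.mean_choroid_thickness <= 0:
            raise ValueError("mean_choroid_thickness must be > 0")

    @property
    def max_intensity(self) -> int:
        return (1 << self.bit_depth) - 1

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def _sinusoid_field(
    shape: tuple[int, ...],
    smoothness: float,
    rng: np.random.Generator,
    n_components: int = 6,
) -> np.ndarray:
    """Sum of low-frequency sinusoids with random phases, normalized to
    max |value| = 1.  Wavelengths are >= `smoothness` along every axis."""
    coords = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    field = np.zeros(shape, dtype=float)
    for _ in range(n_components):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        arg = np.full(shape, phase)
        for ax, c in enumerate(coords):
            # random wavelength in [smoothness, 4*smoothness]
            wavelength = smoothness * rng.uniform(1.0, 4.0)
            arg = arg + 2.0 * np.pi * c / wavelength
        field += rng.uniform(0.3, 1.0) * np.sin(arg)
    peak = np.max(np.abs(field))
    if peak > 0:
        field /= peak
    return field


def sample_boundary_curve(
    width: int,
    mean_row: float,
    smoothness: float,
    amplitude: float,
    seed: int,
    height: int | None = None,
) -> np.ndarray:
    """Sample one smooth boundary curve (row per column).

    The curve is a sum of low-frequency sinusoids with random phases,
    rescaled so the maximum deviation from ``mean_row`` is at most
    ``amplitude`` pixels.  Identical arguments give identical curves.
    """
    if width < 2:
        raise ValueError("width must be >= 2")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if height is not None and not (
        0 < mean_row - amplitude and mean_row + amplitude < height
    ):
        raise ValueError(
            f"curve band [{mean_row - amplitude}, {mean_row + amplitude}] "
            f"exceeds image bounds (0, {height})"
        )
    if amplitude == 0:
        return np.full(width, float(mean_row))
    rng = np.random.default_rng(seed)
    return mean_row + amplitude * _sinusoid_field((width,), smoothness, rng)


def _speckle(rng: np.random.Generator, shape, gamma_shape: float) -> np.ndarray:
    """Unit-mean multiplicative gamma speckle; disabled for non-finite shape."""
    if not np.isfinite(gamma_shape) or gamma_shape <= 0:
        return np.ones(shape)
    return rng.gamma(gamma_shape, 1.0 / gamma_shape, size=shape)


def render_bscan(
    bm_curve: np.ndarray,
    csi_curve: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, BoundaryTrace]:
    """Render one B-scan from its two boundary curves.

    Returns
    -------
    image : ndarray of uint16, shape (height, width)
        Quantized intensities in ``[0, 2**bit_depth - 1]``.
    mask : ndarray of uint8, shape (height, width)
        Choroid mask, 1 for rows in ``[ceil(bm), ceil(csi))``.
    trace : BoundaryTrace
        The generating curves, unchanged.
    """
    bm = np.asarray(bm_curve, dtype=float)
    csi = np.asarray(csi_curve, dtype=float)
    if bm.shape != (config.width,) or csi.shape != (config.width,):
        raise ValueError("curve length must equal config.width")
    if np.any(bm >= csi):
        raise ValueError("BM curve must lie strictly above the CSI curve")
    if np.any(bm < 0) or np.any(csi > config.height):
        raise ValueError("curves out of image bounds")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    rows = np.arange(config.height)[:, None]
    bm_top = np.ceil(bm)[None, :]
    csi_top = np.ceil(csi)[None, :]
    mask = (rows >= bm_top) & (rows < csi_top)

    sclera_level = _CHOROID_LEVEL - _CSI_STEP * config.csi_contrast
    image = np.where(
        rows < bm_top, _RETINA_LEVEL, np.where(mask, _CHOROID_LEVEL, sclera_level)
    ).astype(float)
    image *= _speckle(rng, image.shape, config.speckle_shape)

    qmax = config.max_intensity
    image = np.clip(image, 0.0, 1.0)
    image = np.round(image * qmax).astype(np.uint16)
    return image, mask.astype(np.uint8), BoundaryTrace(bm, csi)


def generate_volume(
    config: SimConfig,
) -> tuple[np.ndarray, list[np.ndarray], list[BoundaryTrace]]:
    """Generate a full synthetic OCT volume with per-slice ground truth.

    BM position and choroid thickness vary smoothly both along columns and
    across slices (a shared low-frequency 2-D field), so adjacent B-scans
    resemble each other the way neighbouring macular raster scans do.
    Deterministic under ``config.seed``.

    Returns ``(volume, masks, traces)`` with ``volume`` of shape
    ``(n_bscans, height, width)`` (uint16).
    """
    rng = np.random.default_rng(config.seed)
    shape2d = (config.n_bscans, config.width)
    mean_bm = config.bm_mean_row_frac * config.height
    bm_field = mean_bm + config.boundary_amplitude * (
        _sinusoid_field(shape2d, config.boundary_smoothness, rng)
        if config.boundary_amplitude > 0
        else np.zeros(shape2d)
    )
    thick_px = config.mean_choroid_thickness / config.axial_spacing
    var_px = config.thickness_variation / config.axial_spacing
    thick_field = thick_px + var_px * (
        _sinusoid_field(shape2d, config.boundary_smoothness, rng)
        if var_px > 0
        else np.zeros(shape2d)
    )
    csi_field = bm_field + thick_field
    if np.any(csi_field > config.height) or np.any(bm_field < 0):
        raise ValueError(
            "rendered boundaries exceed image bounds; increase height or "
            "reduce thickness/amplitude"
        )

    speckle_rng = np.random.default_rng(rng.integers(0, 2**31))
    volume = np.empty((config.n_bscans, config.height, config.width), np.uint16)
    masks: list[np.ndarray] = []
    traces: list[BoundaryTrace] = []
    for s in range(config.n_bscans):
        img, msk, tr = render_bscan(bm_field[s], csi_field[s], config, speckle_rng)
        volume[s] = img
        masks.append(msk)
        traces.append(tr)
    return volume, masks, traces


def write_dataset(out_dir: str | Path, config: SimConfig) -> Path:
    """Generate a volume and write it as per-slice PNGs + CSV traces + JSON
    sidecar (spacings, bit depth, full config).  Returns the output path."""
    from PIL import Image

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    (out / "traces").mkdir(exist_ok=True)
    volume, masks, traces = generate_volume(config)
    for s in range(config.n_bscans):
        name = f"bscan_{s:04d}"
        Image.fromarray(volume[s].astype(np.uint16)).save(
            out / "images" / f"{name}.png"
        )
        Image.fromarray((masks[s] * 255).astype(np.uint8), mode="L").save(
            out / "masks" / f"{name}.png"
        )
        traces[s].to_frame().to_csv(out / "traces" / f"{name}.csv", index=False)
    meta = {
        "axial_spacing_um": config.axial_spacing,
        "lateral_spacing_um": config.lateral_spacing,
        "slice_spacing_um": config.slice_spacing,
        "bit_depth": config.bit_depth,
        "laterality": "OD",
        "sim_config": asdict(config),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    return out
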