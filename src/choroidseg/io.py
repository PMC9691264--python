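"""Volume I/O and cross-validation folds.

The canonical on-disk volume is either a multi-page TIFF or a directory of
ordered PNG/TIFF slices, always accompanied by a JSON metadata sidecar
declaring the pixel spacings (µm), bit depth and eye laterality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["OCTVolume", "load_volume", "save_volume", "make_folds"]

_REQUIRED_META = ("axial_spacing_um", "lateral_spacing_um", "slice_spacing_um",
                  "bit_depth")


@dataclass
class OCTVolume:
    """Ordered stack of B-scans with physical spacing metadata.

    ``data`` holds intensities rescaled to [0, 1] by the declared bit depth,
    shape (n_bscans, height, width).
    """

    data: np.ndarray
    axial_spacing: float
    lateral_spacing: float
    slice_spacing: float
    bit_depth: int
    laterality: str = "OD"

    @property
    def n_bscans(self) -> int:
        return self.data.shape[0]


def _read_meta(meta_path: Path) -> dict:
    if not meta_path.exists():
        raise FileNotFoundError(
            f"metadata sidecar {meta_path} not found; required keys: "
            f"{', '.join(_REQUIRED_META)}"
        )
    meta = json.loads(meta_path.read_text())
    missing = [k for k in _REQUIRED_META if k not in meta]
    if missing:
        raise KeyError(f"metadata missing required keys: {', '.join(missing)}")
    return meta


def load_volume(path: str | Path) -> OCTVolume:
    """Load a volume from a multi-page TIFF or a slice directory.

    Directory slices are ordered lexicographically; a ``meta.json`` sidecar
    must sit next to the TIFF / inside the directory.
    """
    import tifffile
    from PIL import Image

    path = Path(path)
    if path.is_dir():
        meta = _read_meta(path / "meta.json")
        img_dir = path / "images" if (path / "images").is_dir() else path
        files = sorted(p for p in img_dir.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no image slices found under {img_dir}")
        slices = []
        for f in files:
            if f.suffix.lower() == ".png":
                slices.append(np.asarray(Image.open(f)))
            else:
                slices.append(tifffile.imread(f))
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"mixed slice shapes: {sorted(shapes)}")
        stack = np.stack(slices)
    else:
        meta = _read_meta(path.with_suffix(".json"))
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
    qmax = (1 << int(meta["bit_depth"])) - 1
    return OCTVolume(
        data=stack.astype(np.float32) / qmax,
        axial_spacing=float(meta["axial_spacing_um"]),
        lateral_spacing=float(meta["lateral_spacing_um"]),
        slice_spacing=float(meta["slice_spacing_um"]),
        bit_depth=int(meta["bit_depth"]),
        laterality=meta.get("laterality", "OD"),
    )


def save_volume(path: str | Path, volume: np.ndarray, *, axial_spacing: float,
                lateral_spacing: float, slice_spacing: float, bit_depth: int,
                laterality: str = "OD") -> Path:
    """Write raw integer slices as a multi-page TIFF plus a JSON sidecar."""
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(volume, np.uint16))
    meta = {
        "axial_spacing_um": axial_spacing,
        "lateral_spacing_um": lateral_spacing,
        "slice_spacing_um": slice_spacing,
        "bit_depth": bit_depth,
        "laterality": laterality,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def make_folds(n_items: int, k: int = 4, seed: int = 0,
               groups: list | None = None) -> list[dict[str, list[int]]]:
    """Split items into k disjoint near-equal validation folds.

    With ``groups`` (e.g. a volume id per slice), all items of a group share
    a fold.  Deterministic under ``seed``.  Returns one manifest per fold
    with ``train`` and ``val`` index lists.
    """
    rng = np.random.default_rng(seed)
    if groups is not None:
        if len(groups) != n_items:
            raise ValueError("groups must have one entry per item")
        uniq = sorted(set(groups), key=str)
        if len(uniq) < k:
            raise ValueError(f"{len(uniq)} groups cannot fill {k} folds")
        order = rng.permutation(len(uniq))
        fold_of_group = {uniq[g]: int(i % k) for i, g in enumerate(order)}
        fold_of_item = np.array([fold_of_group[g] for g in groups])
    else:
        if n_items < k:
            raise ValueError(f"{n_items} items cannot fill {k} folds")
        fold_of_item = np.empty(n_items, int)
        fold_of_item[rng.permutation(n_items)] = np.arange(n_items) % k
    manifests = []
    for f in range(k):
        val = np.nonzero(fold_of_item == f)[0]
        train = np.nonzero(fold_of_item != f)[0]
        manifests.append({"train": train.tolist(), "val": val.tolist()})
    return manifests
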