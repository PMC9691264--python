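"""Choroidal morphometry: en-face thickness maps, ETDRS subfield statistics,
3-D point-cloud reconstruction, and volume / surface-area / curvature
features with a two-group comparison report.

The ETDRS grid divides the macula into 9 subfields by concentric circles of
1, 3 and 6 mm diameter: a central foveal disk (CFT), and inner (1–3 mm) and
outer (3–6 mm) annuli each split into superior / inferior / nasal / temporal
quadrants along the ±45° diagonals.  Nasal and temporal depend on eye
laterality: for a right eye (OD) the nasal retina maps to the +column side
of the en-face grid, for a left eye (OS) to the −column side.  Subfield
masks are drawn directly in physical (mm) coordinates of the grid cells, so
circles are circular regardless of grid anisotropy and the 9 subfields
partition the 6 mm disk exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .trace import BoundaryTrace

__all__ = [
    "ThicknessMap",
    "ETDRSReport",
    "Surface3DFeatures",
    "thickness_map",
    "etdrs_subfields",
    "surfaces_to_point_cloud",
    "choroid_volume",
    "surface_area",
    "surface_curvature",
    "compute_surface_features",
    "compare_groups",
]

SUBFIELD_NAMES = ("CFT", "SIM", "NIM", "IIM", "TIM", "SOM", "NOM", "IOM", "TOM")


@dataclass
class ThicknessMap:
    """En-face choroidal thickness grid (n_bscans x width) in µm.

    ``values[s, c]`` is the thickness at slice s, column c; NaN marks
    missing columns.  ``center`` is the (slice, column) taken as the fovea,
    defaulting to the geometric center of the grid (macula-centered
    acquisition).
    """

    values: np.ndarray
    lateral_spacing: float  # µm/px along columns
    slice_spacing: float    # µm between B-scans
    center: tuple[float, float] | None = None
    laterality: str = "OD"

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("thickness map must be 2-D (n_bscans x width)")
        if min(self.lateral_spacing, self.slice_spacing) <= 0:
            raise ValueError("spacings must be > 0")
        if np.nanmin(self.values, initial=0.0) < 0:
            raise ValueError("thickness must be >= 0 where present")
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be 'OD' or 'OS'")
        if self.center is None:
            self.center = ((self.values.shape[0] - 1) / 2.0,
                           (self.values.shape[1] - 1) / 2.0)

    def physical_offsets_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(dy, dx) offsets of every cell from the center, in mm; dy along
        slices, dx along columns."""
        s = (np.arange(self.values.shape[0]) - self.center[0]) * self.slice_spacing
        c = (np.arange(self.values.shape[1]) - self.center[1]) * self.lateral_spacing
        dy, dx = np.meshgrid(s / 1000.0, c / 1000.0, indexing="ij")
        return dy, dx


@dataclass
class ETDRSReport:
    center_point_thickness: float
    subfield_means: dict[str, float]
    subfield_coverage: dict[str, float]
    global_average: float


@dataclass
class Surface3DFeatures:
    inner_volume: float        # mm^3
    inner_surface_area: float  # mm^2 (CSI surface)
    bm_surface_area: float     # mm^2
    bm_curvature: float        # mm^-1
    csi_curvature: float       # mm^-1
    roi: tuple[float, float]   # width x depth, mm


def thickness_map(
    traces: list[BoundaryTrace],
    axial_spacing: float,
    lateral_spacing: float,
    slice_spacing: float,
    laterality: str = "OD",
    center: tuple[float, float] | None = None,
) -> ThicknessMap:
    """Stack per-slice traces into an en-face thickness grid in µm."""
    if not traces:
        raise ValueError("traces must be nonempty")
    widths = {t.width for t in traces}
    if len(widths) != 1:
        raise ValueError("all traces must share a common width")
    values = np.stack([t.thickness_px() * axial_spacing for t in traces])
    return ThicknessMap(values, lateral_spacing, slice_spacing,
                        center=center, laterality=laterality)


def _quadrant_masks(dy: np.ndarray, dx: np.ndarray, laterality: str):
    """Superior/inferior along the slice axis, nasal/temporal along columns,
    split on the ±45° diagonals.  Ties on the diagonals go to the
    superior/inferior wedges (a zero-measure choice)."""
    nasal_sign = 1.0 if laterality == "OD" else -1.0
    sup = (dy <= -np.abs(dx))
    inf = (dy >= np.abs(dx)) & ~sup
    nas = (nasal_sign * dx > np.abs(dy))
    tem = (-nasal_sign * dx > np.abs(dy))
    return {"S": sup, "I": inf, "N": nas, "T": tem}


def etdrs_subfields(t: ThicknessMap) -> ETDRSReport:
    """ETDRS 9-subfield means, center-point thickness and the 6 mm-disk
    global average; missing cells are excluded per subfield and coverage
    reported."""
    dy, dx = t.physical_offsets_mm()
    r = np.hypot(dy, dx)
    if r.min() > 0.5:
        raise ValueError("grid does not cover the central 1 mm circle")
    half_extent = (np.abs(dy).max(), np.abs(dx).max())
    if min(half_extent) < 0.5:
        raise ValueError("grid physical extent smaller than the 1 mm circle")

    quads = _quadrant_masks(dy, dx, t.laterality)
    inner = (r > 0.5) & (r <= 1.5)
    outer = (r > 1.5) & (r <= 3.0)
    masks = {"CFT": r <= 0.5}
    for ring_name, ring in (("I", inner), ("O", outer)):
        for q in "SNIT":
            masks[f"{q}{ring_name}M"] = ring & quads[q]

    values = t.values
    present = np.isfinite(values)
    means, coverage = {}, {}
    for name in SUBFIELD_NAMES:
        sel = masks[name]
        n_cells = int(sel.sum())
        n_ok = int((sel & present).sum())
        coverage[name] = n_ok / n_cells if n_cells else 0.0
        if n_ok == 0:
            warnings.warn(f"ETDRS subfield {name} has no valid cells")
            means[name] = np.nan
        else:
            means[name] = float(np.nanmean(np.where(sel, values, np.nan)))

    ci, cj = int(round(t.center[0])), int(round(t.center[1]))
    cpt = float(values[ci, cj])
    disk = (r <= 3.0) & present
    global_avg = float(values[disk].mean()) if disk.any() else np.nan
    return ETDRSReport(cpt, means, coverage, global_avg)


def surfaces_to_point_cloud(
    traces: list[BoundaryTrace],
    axial_spacing: float,
    lateral_spacing: float,
    slice_spacing: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One 3-D point (x, y, z) in mm per defined (slice, column, boundary):
    x = column * lateral, y = slice * slice_spacing, z = row * axial."""
    if min(axial_spacing, lateral_spacing, slice_spacing) <= 0:
        raise ValueError("spacings must be > 0")
    clouds = []
    for rows_of in ("bm_rows", "csi_rows"):
        pts = []
        for s, tr in enumerate(traces):
            rows = getattr(tr, rows_of)
            cols = np.nonzero(np.isfinite(rows))[0]
            pts.append(np.column_stack([
                cols * lateral_spacing,
                np.full(len(cols), s * slice_spacing),
                rows[cols] * axial_spacing,
            ]))
        clouds.append(np.concatenate(pts, axis=0) / 1000.0)
    return clouds[0], clouds[1]


def _roi_mask(t: ThicknessMap, roi: tuple[float, float]) -> np.ndarray:
    dy, dx = t.physical_offsets_mm()
    half_w, half_d = roi[0] / 2.0, roi[1] / 2.0
    if half_w - 1e-9 > np.abs(dx).max() or half_d - 1e-9 > np.abs(dy).max():
        raise ValueError("ROI extends outside the en-face grid")
    return (np.abs(dx) <= half_w) & (np.abs(dy) <= half_d)


def choroid_volume(t: ThicknessMap, roi: tuple[float, float] = (3.0, 3.0)
                   ) -> float:
    """Choroid volume in mm³ over an axis-aligned fovea-centered ROI
    (width mm x depth mm): rectangle-rule sum of thickness times cell area.
    Missing cells contribute 0."""
    sel = _roi_mask(t, roi)
    vals = np.where(np.isfinite(t.values), t.values, 0.0)
    cell_area = (t.lateral_spacing / 1000.0) * (t.slice_spacing / 1000.0)
    return float(vals[sel].sum() / 1000.0 * cell_area)


def _height_grid(trace_rows: np.ndarray, axial_spacing: float) -> np.ndarray:
    return trace_rows * axial_spacing / 1000.0


def surface_area(heights_mm: np.ndarray, lateral_mm: float, slice_mm: float
                 ) -> float:
    """Area (mm²) of a height field z(slice, column): each grid cell is
    split into two triangles and their areas summed.  Cells touching a NaN
    vertex are skipped."""
    z = np.asarray(heights_mm, float)
    if z.ndim != 2 or z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("need a height field of at least 2x2 defined points")
    ns, nc = z.shape
    x = np.arange(nc) * lateral_mm
    y = np.arange(ns) * slice_mm
    xx, yy = np.meshgrid(x, y)
    p = np.stack([xx, yy, z], axis=-1)
    a, b, c, d = p[:-1, :-1], p[:-1, 1:], p[1:, :-1], p[1:, 1:]

    def tri_area(u, v, w):
        cross = np.cross(v - u, w - u)
        area = 0.5 * np.linalg.norm(cross, axis=-1)
        return np.where(np.isfinite(area), area, 0.0)

    total = tri_area(a, b, c) + tri_area(b, d, c)
    if not np.isfinite(total).any() or total.sum() == 0:
        raise ValueError("no fully defined grid cell")
    return float(np.nansum(total))


def surface_curvature(
    heights_mm: np.ndarray,
    lateral_mm: float,
    slice_mm: float,
    window_mm: float = 1.0,
) -> float:
    """Mean absolute mean-curvature (mm⁻¹) of a height field.

    A second-order polynomial z = a + bx + cy + dx² + exy + fy² is fitted by
    least squares in sliding windows (stride = half window); the mean
    curvature of the fitted quadric is evaluated at each window center and
    its absolute value averaged.  Degenerate windows (rank-deficient fits or
    missing data) are skipped with a warning.
    """
    z = np.asarray(heights_mm, float)
    wy = max(3, int(round(window_mm / slice_mm)))
    wx = max(3, int(round(window_mm / lateral_mm)))
    if z.shape[0] < wy or z.shape[1] < wx:
        raise ValueError("grid smaller than the curvature window")
    xs = (np.arange(wx) - (wx - 1) / 2.0) * lateral_mm
    ys = (np.arange(wy) - (wy - 1) / 2.0) * slice_mm
    gx, gy = np.meshgrid(xs, ys)
    design = np.column_stack([
        np.ones(gx.size), gx.ravel(), gy.ravel(),
        gx.ravel() ** 2, (gx * gy).ravel(), gy.ravel() ** 2,
    ])
    pinv = np.linalg.pinv(design)

    curvs = []
    skipped = 0
    for i0 in range(0, z.shape[0] - wy + 1, max(1, wy // 2)):
        for j0 in range(0, z.shape[1] - wx + 1, max(1, wx // 2)):
            patch = z[i0:i0 + wy, j0:j0 + wx].ravel()
            if not np.isfinite(patch).all():
                skipped += 1
                continue
            a0, b, c, d, e, f = pinv @ patch
            zx, zy, zxx, zxy, zyy = b, c, 2 * d, e, 2 * f
            denom = (1 + zx**2 + zy**2) ** 1.5
            h = ((1 + zy**2) * zxx - 2 * zx * zy * zxy + (1 + zx**2) * zyy) / (
                2 * denom
            )
            curvs.append(abs(h))
    if skipped:
        warnings.warn(f"{skipped} curvature windows skipped (missing data)")
    if not curvs:
        raise ValueError("no valid curvature window")
    return float(np.mean(curvs))


def compute_surface_features(
    traces: list[BoundaryTrace],
    axial_spacing: float,
    lateral_spacing: float,
    slice_spacing: float,
    roi: tuple[float, float] = (3.0, 3.0),
    laterality: str = "OD",
    curvature_window_mm: float = 1.0,
) -> Surface3DFeatures:
    """Volume, surface areas and curvatures of the reconstructed choroid.

    "Inner" follows the convention that the choroid interior is bounded by
    BM above and CSI below; the inner surface area is computed on the CSI
    height field (the BM area is reported alongside).  All quantities are
    restricted to the fovea-centered ROI.
    """
    t = thickness_map(traces, axial_spacing, lateral_spacing, slice_spacing,
                      laterality=laterality)
    sel = _roi_mask(t, roi)
    rows_sel = np.unique(np.nonzero(sel.any(axis=1))[0])
    cols_sel = np.unique(np.nonzero(sel.any(axis=0))[0])
    bm = np.stack([tr.bm_rows for tr in traces])[np.ix_(rows_sel, cols_sel)]
    csi = np.stack([tr.csi_rows for tr in traces])[np.ix_(rows_sel, cols_sel)]
    lat_mm, sl_mm = lateral_spacing / 1000.0, slice_spacing / 1000.0
    bm_h = _height_grid(bm, axial_spacing)
    csi_h = _height_grid(csi, axial_spacing)
    return Surface3DFeatures(
        inner_volume=choroid_volume(t, roi),
        inner_surface_area=surface_area(csi_h, lat_mm, sl_mm),
        bm_surface_area=surface_area(bm_h, lat_mm, sl_mm),
        bm_curvature=surface_curvature(bm_h, lat_mm, sl_mm,
                                       curvature_window_mm),
        csi_curvature=surface_curvature(csi_h, lat_mm, sl_mm,
                                        curvature_window_mm),
        roi=roi,
    )


def compare_groups(a: dict[str, list[float]] | "object",
                   b: dict[str, list[float]] | "object"):
    """Welch two-sample comparison of per-subject measures between groups.

    ``a`` and ``b`` map measure names to per-subject values (group ``a`` is
    the reference: mean difference = mean(b) - mean(a)).  Returns a
    DataFrame with group means, SDs, the mean difference, the Welch t-test
    p-value and the 95% confidence interval of the difference.  Groups of
    size 1 get means only, flagged in the ``note`` column.
    """
    import pandas as pd

    if not a or not b:
        raise ValueError("both groups must be nonempty")
    rows = []
    for measure in a:
        xa = np.asarray(a[measure], float)
        xb = np.asarray(b[measure], float)
        row = {
            "measure": measure,
            "mean_a": xa.mean(), "sd_a": xa.std(ddof=1) if len(xa) > 1 else np.nan,
            "mean_b": xb.mean(), "sd_b": xb.std(ddof=1) if len(xb) > 1 else np.nan,
            "mean_difference": xb.mean() - xa.mean(),
        }
        if len(xa) < 2 or len(xb) < 2:
            row.update(p_value=np.nan, ci_low=np.nan, ci_high=np.nan,
                       note="group of size 1: no test")
        elif xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
            same = xa.mean() == xb.mean()
            row.update(p_value=1.0 if same else 0.0, ci_low=row["mean_difference"],
                       ci_high=row["mean_difference"],
                       note="zero variance in both groups")
        else:
            res = stats.ttest_ind(xb, xa, equal_var=False)
            va, vb = xa.var(ddof=1) / len(xa), xb.var(ddof=1) / len(xb)
            se = np.sqrt(va + vb)
            df = (va + vb) ** 2 / (
                va**2 / (len(xa) - 1) + vb**2 / (len(xb) - 1)
            )
            tcrit = stats.t.ppf(0.975, df)
            row.update(p_value=float(res.pvalue),
                       ci_low=row["mean_difference"] - tcrit * se,
                       ci_high=row["mean_difference"] + tcrit * se, note="")
        rows.append(row)
    return pd.DataFrame(rows)
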