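"""Boundary key points and Gaussian soft point maps.

Key points selected on the BM and CSI boundary curves are turned into a soft
point map: at pixel ``(i, j)`` (``i`` = column, ``j`` = row) the map holds

    S[i, j] = max_k exp(-((i - x_k)^2 + (j - y_k)^2) / (2 sigma^2))

the *maximum* (not sum) over Gaussian bumps centred on the K selected points,
so the map stays in (0, 1] and attains exactly 1 at integer-coordinate key
points.  These maps act as auxiliary ground truth for boundary supervision:
the network's per-layer boundary point maps are regressed onto max-pooled
versions of the full-resolution map.

Two selection strategies are provided: ``uniform`` (equally spaced in arc
length along the boundary polyline, the default) and ``curvature`` (local
maxima of the absolute discrete curvature, padded with uniform points when
the boundary is too straight to supply enough extrema).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import BoundaryTrace

__all__ = [
    "KeyPoint",
    "SoftPointMap",
    "select_boundary_points",
    "render_soft_point_map",
    "downsample_point_map",
]


@dataclass(frozen=True)
class KeyPoint:
    """One selected boundary point: ``x`` column, ``y`` row, source boundary."""

    x: float
    y: float
    boundary: str = "BM"  # "BM" or "CSI"


@dataclass
class SoftPointMap:
    """H x W soft point map plus the points and sigma that produced it."""

    values: np.ndarray
    points: list
    sigma: float

    @property
    def K(self) -> int:
        return len(self.points)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _uniform_arclength_indices(cols: np.ndarray, rows: np.ndarray, k: int) -> np.ndarray:
    """Indices of k points equally spaced in arc length along the polyline.

    Halfway targets round down, so a straight boundary of width m with k=3
    yields columns {0, floor((m-1)/2), m-1}.
    """
    if k == 1:
        return np.array([0])
    seg = np.hypot(np.diff(cols.astype(float)), np.diff(rows.astype(float)))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, cum[-1], k)
    pos = np.interp(targets, cum, np.arange(len(cols), dtype=float))
    return np.ceil(pos - 0.5).astype(int)  # round half down


def _curvature_extrema(rows: np.ndarray) -> np.ndarray:
    """Interior indices of local maxima of |second difference|, strongest
    first, ties broken leftmost."""
    if len(rows) < 3:
        return np.array([], dtype=int)
    curv = np.abs(rows[:-2] - 2.0 * rows[1:-1] + rows[2:])  # index i -> column i+1
    is_max = np.ones(len(curv), dtype=bool)
    is_max[1:] &= curv[1:] > curv[:-1]  # plateau -> leftmost wins
    is_max[:-1] &= curv[:-1] >= curv[1:]
    cand = np.nonzero(is_max & (curv > 1e-12))[0]
    order = np.lexsort((cand, -curv[cand]))  # value desc, column asc on ties
    return cand[order] + 1


def _select_on_boundary(
    cols: np.ndarray, rows: np.ndarray, k: int, strategy: str, name: str
) -> list[KeyPoint]:
    uniform_idx = _uniform_arclength_indices(cols, rows, k)
    if strategy == "uniform":
        idx = uniform_idx
    elif strategy == "curvature":
        idx = _curvature_extrema(rows)[:k]
        if len(idx) < k:  # pad with uniform points on unused columns
            pad = [i for i in uniform_idx if i not in set(idx)]
            idx = np.concatenate([idx, pad[: k - len(idx)]]).astype(int)
        idx = np.sort(idx)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return [KeyPoint(float(cols[i]), float(rows[i]), name) for i in idx]


def select_boundary_points(
    trace: BoundaryTrace, k_per_boundary: int, strategy: str = "uniform"
) -> list[KeyPoint]:
    """Select ``k_per_boundary`` key points on BM and on CSI. Deterministic."""
    if k_per_boundary < 1:
        raise ValueError("k_per_boundary must be >= 1")
    points: list[KeyPoint] = []
    for name, rows in (("BM", trace.bm_rows), ("CSI", trace.csi_rows)):
        cols = np.nonzero(np.isfinite(rows))[0]
        if len(cols) < k_per_boundary:
            raise ValueError(
                f"{name} boundary has {len(cols)} valid columns, "
                f"fewer than k_per_boundary={k_per_boundary}"
            )
        points.extend(
            _select_on_boundary(cols, rows[cols], k_per_boundary, strategy, name)
        )
    return points


def render_soft_point_map(
    points: list[KeyPoint], shape: tuple[int, int], sigma: float
) -> SoftPointMap:
    """Render the Gaussian soft point map (max over points) on an H x W grid."""
    if not points:
        raise ValueError("points must be non-empty")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    h, w = shape
    jj, ii = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                         indexing="ij")
    d2min = np.full((h, w), np.inf)
    for p in points:
        d2 = (ii - p.x) ** 2 + (jj - p.y) ** 2
        np.minimum(d2min, d2, out=d2min)
    values = np.exp(-d2min / (2.0 * sigma**2))
    return SoftPointMap(values, list(points), float(sigma))


def downsample_point_map(pmap: SoftPointMap, factor: int) -> SoftPointMap:
    """Block-maximum pooling by a power-of-two ``factor``; peak values of 1
    survive at every scale.  Point coordinates are divided by the factor."""
    if factor < 1 or (factor & (factor - 1)):
        raise ValueError("factor must be a positive power of two")
    h, w = pmap.values.shape
    if h % factor or w % factor:
        raise ValueError(f"factor {factor} does not divide shape {h}x{w}")
    if factor == 1:
        return SoftPointMap(pmap.values.copy(), list(pmap.points), pmap.sigma)
    v = pmap.values.reshape(h // factor, factor, w // factor, factor).max(axis=(1, 3))
    pts = [KeyPoint(p.x / factor, p.y / factor, p.boundary) for p in pmap.points]
    return SoftPointMap(v, pts, pmap.sigma / factor)
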