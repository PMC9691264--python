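"""Per-column boundary coordinates of one B-scan.

A :class:`BoundaryTrace` records, for every image column, the row position of
Bruch's membrane (BM, the upper choroid boundary) and of the choroidal–scleral
interface (CSI, the lower boundary).  Rows are real-valued; row index 0 is the
top of the B-scan and depth increases downward.  Columns where a boundary
could not be determined hold NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BoundaryTrace"]


@dataclass
class BoundaryTrace:
    """BM and CSI row coordinates per column of a single B-scan.

    Parameters
    ----------
    bm_rows, csi_rows : ndarray of float, shape (width,)
        Row coordinate of each boundary per column; NaN marks a missing
        column.  Where both are present ``bm_rows <= csi_rows``.
    """

    bm_rows: np.ndarray
    csi_rows: np.ndarray

    def __post_init__(self) -> None:
        self.bm_rows = np.asarray(self.bm_rows, dtype=float)
        self.csi_rows = np.asarray(self.csi_rows, dtype=float)
        if self.bm_rows.shape != self.csi_rows.shape or self.bm_rows.ndim != 1:
            raise ValueError("bm_rows and csi_rows must be 1-D of equal length")
        both = np.isfinite(self.bm_rows) & np.isfinite(self.csi_rows)
        if np.any(self.bm_rows[both] > self.csi_rows[both] + 1e-9):
            raise ValueError("BM must lie above (<=) CSI wherever both are defined")

    @property
    def width(self) -> int:
        return self.bm_rows.shape[0]

    @property
    def valid(self) -> np.ndarray:
        """Columns where both boundaries are defined."""
        return np.isfinite(self.bm_rows) & np.isfinite(self.csi_rows)

    def thickness_px(self) -> np.ndarray:
        """Choroid thickness per column in pixels (NaN where missing)."""
        return self.csi_rows - self.bm_rows

    def to_frame(self):
        """Tabular (column, bm_row, csi_row) representation."""
        import pandas as pd

        return pd.DataFrame(
            {
                "column": np.arange(self.width),
                "bm_row": self.bm_rows,
                "csi_row": self.csi_rows,
            }
        )

    @classmethod
    def from_frame(cls, df) -> "BoundaryTrace":
        df = df.sort_values("column")
        return cls(df["bm_row"].to_numpy(float), df["csi_row"].to_numpy(float))
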