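"""Square-cell raster container used by every pipeline stage.

All layers of one scene share a single grid geometry: planar projected
coordinates in metres, origin at the lower-left corner, row index increasing
northwards and column index increasing eastwards. Cell (r, c) has its centre
at (x0 + (c + 0.5) * cell_size, y0 + (r + 0.5) * cell_size).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["GridRaster", "require_same_grid", "require_boolean"]


@dataclass(frozen=True)
class GridRaster:
    """A georeferenced square-cell raster (elevation, class codes, counts or masks)."""

    data: np.ndarray
    cell_size: float = 10.0
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise ValueError(f"raster data must be 2-D, got shape {arr.shape}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        object.__setattr__(self, "data", arr)

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def same_grid(self, other: "GridRaster") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.x0 == other.x0
            and self.y0 == other.y0
        )

    def with_data(self, data: np.ndarray) -> "GridRaster":
        """New raster on the same grid geometry."""
        return replace(self, data=np.asarray(data))

    # -- coordinate transforms ---------------------------------------------
    def cell_center(self, rows, cols) -> tuple[np.ndarray, np.ndarray]:
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        x = self.x0 + (cols + 0.5) * self.cell_size
        y = self.y0 + (rows + 0.5) * self.cell_size
        return x, y

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing planar point(s) (x, y)."""
        col = np.floor((np.asarray(x) - self.x0) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.y0) / self.cell_size).astype(int)
        return row, col

    def contains_point(self, x, y) -> np.ndarray:
        row, col = self.cell_of(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    # -- mask helpers -------------------------------------------------------
    def count_true(self) -> int:
        return int(np.count_nonzero(self.data))

    def area_km2(self) -> float:
        """Area covered by truthy cells."""
        return self.count_true() * self.cell_area_km2


def require_same_grid(*rasters: GridRaster) -> None:
    first = rasters[0]
    for r in rasters[1:]:
        if not first.same_grid(r):
            raise ValueError(
                "rasters do not share one grid geometry: "
                f"{first.shape}/{first.cell_size} vs {r.shape}/{r.cell_size}"
            )


def require_boolean(raster: GridRaster, name: str = "raster") -> None:
    if raster.data.dtype != np.bool_:
        raise ValueError(f"{name} must be a boolean raster, got dtype {raster.data.dtype}")
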