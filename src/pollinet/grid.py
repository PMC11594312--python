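"""Shared raster geometry.

All layers in a run must live on one north-up WGS84 grid of square cells.
The grid is described by the latitude/longitude of the north-west corner,
a cell size in decimal degrees, and the raster shape. Row 0 is the
northernmost row; latitude decreases as the row index grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Alignment tolerance in decimal degrees. Two grids closer than this in
#: every geometric field are treated as the same grid; anything else is an
#: error — no silent resampling, ever.
ALIGN_TOL = 1e-9

WGS84 = "EPSG:4326"


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up geographic raster with square cells."""

    n_rows: int
    n_cols: int
    origin_lat: float
    origin_lon: float
    cell_size: float
    crs_id: str = field(default=WGS84)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(f"grid shape must be >= 1x1, got {self.n_rows}x{self.n_cols}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.crs_id != WGS84:
            raise ValueError(f"only geographic WGS84 ({WGS84}) grids are supported, got {self.crs_id!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def aligned_with(self, other: "GridSpec") -> bool:
        """True iff the two grids coincide within ``ALIGN_TOL`` degrees."""
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.origin_lat - other.origin_lat) <= ALIGN_TOL
            and abs(self.origin_lon - other.origin_lon) <= ALIGN_TOL
            and abs(self.cell_size - other.cell_size) <= ALIGN_TOL
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lat, lon) of the center of cell (row, col); north-up row order."""
        if not (0 <= row < self.n_rows):
            raise IndexError(f"row {row} outside [0, {self.n_rows})")
        if not (0 <= col < self.n_cols):
            raise IndexError(f"col {col} outside [0, {self.n_cols})")
        lat = self.origin_lat - (row + 0.5) * self.cell_size
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        return (lat, lon)

    def nearest_cell(self, lat: float, lon: float) -> tuple[int, int]:
        """(row, col) of the cell whose extent contains the point.

        Points on a cell boundary resolve to the cell south/east of the
        boundary, matching the floor convention of most raster packages.
        Raises ``IndexError`` for points outside the grid extent.
        """
        row = int((self.origin_lat - lat) / self.cell_size)
        col = int((lon - self.origin_lon) / self.cell_size)
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"point ({lat}, {lon}) falls outside the grid")
        return (row, col)


def cell_center(grid: GridSpec, row: int, col: int) -> tuple[float, float]:
    """Functional alias for :meth:`GridSpec.cell_center`."""
    return grid.cell_center(row, col)
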