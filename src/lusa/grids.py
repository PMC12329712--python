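"""Grid geometry shared by every raster-valued stage.

All stages operate on a single rectangular grid in a Cartesian equal-area
pseudo-CRS: coordinates are metres, cells are squares, the origin of the
coordinate frame is the lower-left corner of the grid and rows run top-down
(row 0 is the northernmost row).  Real-geographic reprojection is out of
scope; the geometry exists so that point records (occurrences, pseudo-
absences) and rasters can be related unambiguously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GeometryMismatchError(ValueError):
    """Two rasters that must share a grid do not."""


@dataclass(frozen=True)
class GridGeometry:
    """Shape, cell size and placement of a raster grid.

    Parameters
    ----------
    shape
        (rows, cols).
    cell_area
        Area of one cell in hectares (> 0).  The cell side length in metres
        is derived from it (1 ha = 10^4 m^2).
    origin
        (x0, y_top): world coordinates of the upper-left corner, metres.
    """

    shape: tuple[int, int]
    cell_area: float = 10_000.0
    origin: tuple[float, float] = field(default=(0.0, 0.0))

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows <= 0 or cols <= 0:
            raise ValueError(f"grid shape must be positive, got {self.shape}")
        if self.cell_area <= 0:
            raise ValueError(f"cell_area must be > 0 ha, got {self.cell_area}")

    @property
    def n_cells(self) -> int:
        return self.shape[0] * self.shape[1]

    @property
    def cell_size(self) -> float:
        """Cell side length in metres."""
        return float(np.sqrt(self.cell_area * 1e4))

    @property
    def y_top(self) -> float:
        return self.origin[1] + self.shape[0] * self.cell_size

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map world coordinates to (row, col); cells index from top-left."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((self.y_top - y) / self.cell_size).astype(int)
        return row, col

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.cell_of(x, y)
        return (
            (row >= 0)
            & (row < self.shape[0])
            & (col >= 0)
            & (col < self.shape[1])
        )

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        s = self.cell_size
        x = self.origin[0] + (np.asarray(col) + 0.5) * s
        y = self.y_top - (np.asarray(row) + 0.5) * s
        return x, y

    def check_same(self, other: "GridGeometry") -> None:
        if self != other:
            raise GeometryMismatchError(
                f"grid geometries differ: {self} vs {other}"
            )


@dataclass
class CategoricalMap:
    """Integer-coded categorical raster (biome, climate zone, soil, state)."""

    values: np.ndarray  # int array, shape = geometry.shape
    labels: list[str]
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.shape != self.geometry.shape:
            raise GeometryMismatchError(
                f"map shape {self.values.shape} != geometry {self.geometry.shape}"
            )
        if self.values.min() < 0 or self.values.max() >= len(self.labels):
            raise ValueError("categorical codes outside label range")

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def label_at(self, row: int, col: int) -> str:
        return self.labels[self.values[row, col]]
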