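"""Core georeferencing types shared across the pipeline.

Pixel convention used everywhere in this package: 0-based indices, half-open
intervals, row axis pointing southward (increasing row = decreasing projected
y). A raster's geotransform anchors the *upper-left corner* of pixel (0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np


@dataclass(frozen=True)
class GeoTransform:
    """Affine north-up geotransform in projected metric coordinates.

    Parameters
    ----------
    origin_x, origin_y:
        Projected coordinates (m) of the raster's upper-left corner.
    gsd_x, gsd_y:
        Pixel size in metres. Both positive; ``gsd_y`` is applied southward
        (y decreases with increasing row index).
    """

    origin_x: float
    origin_y: float
    gsd_x: float
    gsd_y: float

    def __post_init__(self) -> None:
        if self.gsd_x <= 0 or self.gsd_y <= 0:
            raise ValueError("gsd_x and gsd_y must be positive")

    def pixel_to_xy(self, row, col):
        """Projected coordinates of the upper-left corner of pixel (row, col)."""
        x = self.origin_x + np.asarray(col) * self.gsd_x
        y = self.origin_y - np.asarray(row) * self.gsd_y
        return x, y

    def xy_to_pixel(self, x, y):
        """Fractional (row, col) of projected point (x, y)."""
        col = (np.asarray(x) - self.origin_x) / self.gsd_x
        row = (self.origin_y - np.asarray(y)) / self.gsd_y
        return row, col

    def cell_centers(self, shape):
        """Projected (x, y) grids of the cell centers of a raster of ``shape``."""
        rows = np.arange(shape[0]) + 0.5
        cols = np.arange(shape[1]) + 0.5
        x = self.origin_x + cols * self.gsd_x
        y = self.origin_y - rows * self.gsd_y
        return np.meshgrid(x, y)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle in projected metric coordinates."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    source_tp: Optional[Union[int, str]] = None

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError(
                f"degenerate bounding box: ({self.xmin}, {self.ymin}, "
                f"{self.xmax}, {self.ymax})"
            )

    @property
    def center(self) -> tuple:
        return ((self.xmin + self.xmax) / 2.0, (self.ymin + self.ymax) / 2.0)

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    def intersection_area(self, other: "BoundingBox") -> float:
        w = min(self.xmax, other.xmax) - max(self.xmin, other.xmin)
        h = min(self.ymax, other.ymax) - max(self.ymin, other.ymin)
        if w <= 0 or h <= 0:
            return 0.0
        return w * h

    def contains(self, other: "BoundingBox", tol: float = 1e-12) -> bool:
        return (
            self.xmin <= other.xmin + tol
            and self.ymin <= other.ymin + tol
            and self.xmax >= other.xmax - tol
            and self.ymax >= other.ymax - tol
        )

    def padded(self, pad_x: float, pad_y: float = None) -> "BoundingBox":
        if pad_y is None:
            pad_y = pad_x
        return BoundingBox(
            self.xmin - pad_x, self.ymin - pad_y,
            self.xmax + pad_x, self.ymax + pad_y,
            source_tp=self.source_tp,
        )


@dataclass
class RasterLayer:
    """Single-band georeferenced raster; NaN marks missing cells."""

    values: np.ndarray
    gt: GeoTransform
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("RasterLayer values must be 2-D")

    @property
    def shape(self):
        return self.values.shape

    def same_geometry(self, other: "RasterLayer") -> bool:
        return self.shape == other.shape and self.gt == other.gt
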