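"""Regions of interest in the sample plane.

All coordinates are in nanometres. Rectangles are half-open on both axes,
``[x_min, x_max) x [y_min, y_max)``, so that a tiling of rectangles
partitions a point set exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from matplotlib.path import Path


@dataclass(frozen=True)
class RectangleROI:
    """Axis-aligned rectangle, half-open on both axes."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("rectangle ROI must have positive area")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x_min)
            & (x < self.x_max)
            & (y >= self.y_min)
            & (y < self.y_max)
        )

    def intersection(self, other: "RectangleROI") -> "RectangleROI":
        return RectangleROI(
            max(self.x_min, other.x_min),
            min(self.x_max, other.x_max),
            max(self.y_min, other.y_min),
            min(self.y_max, other.y_max),
        )


@dataclass(frozen=True)
class CircleROI:
    """Disk of radius ``r`` (nm) centred at (cx, cy); boundary included."""

    cx: float
    cy: float
    r: float

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError("circle ROI must have positive radius")

    @property
    def area(self) -> float:
        return float(np.pi * self.r**2)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.r**2


class PolygonROI:
    """Simple polygon given by its vertices (nm), implicitly closed."""

    def __init__(self, vertices: Sequence[Tuple[float, float]]):
        vertices = np.asarray(vertices, dtype=float)
        if vertices.ndim != 2 or vertices.shape[0] < 3 or vertices.shape[1] != 2:
            raise ValueError("polygon needs >= 3 (x, y) vertices")
        self.vertices = vertices
        # implicit closure: Path treats the vertex list as a closed ring
        # (closed=True would consume the last vertex as a close marker)
        self._path = Path(vertices)
        # shoelace area; guards against degenerate (zero-area) polygons
        x, y = vertices[:, 0], vertices[:, 1]
        self.area = float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)
        if self.area <= 0:
            raise ValueError("polygon ROI must have positive area")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        pts = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])
        return self._path.contains_points(pts)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PolygonROI({len(self.vertices)} vertices, area={self.area:.1f} nm^2)"
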