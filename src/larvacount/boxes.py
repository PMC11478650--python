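"""Axis-aligned boxes in pixel coordinates.

One convention everywhere: the origin is the top-left image corner, x grows
rightwards, y grows downwards, and boxes are half-open intervals
``[x_min, x_max) x [y_min, y_max)``.  A 10x10 head box centred on pixel
column ``cx`` is therefore ``(cx-5, cy-5, cx+5, cy+5)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple


@dataclass(frozen=True, slots=True)
class Box:
    """An axis-aligned rectangle, the unit of detection and ground truth."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box: {self!r}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> Tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def translate(self, dx: float, dy: float) -> "Box":
        return Box(self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy)

    def intersects(self, other: "Box") -> bool:
        return (
            self.x_min < other.x_max
            and other.x_min < self.x_max
            and self.y_min < other.y_max
            and other.y_min < self.y_max
        )

    def intersection(self, other: "Box") -> Optional["Box"]:
        """Overlap of two boxes, or None when they are disjoint."""
        x0 = max(self.x_min, other.x_min)
        y0 = max(self.y_min, other.y_min)
        x1 = min(self.x_max, other.x_max)
        y1 = min(self.y_max, other.y_max)
        if x0 < x1 and y0 < y1:
            return Box(x0, y0, x1, y1)
        return None

    def clip(self, bounds: "Box") -> Optional["Box"]:
        """Alias of :meth:`intersection`, named for clipping to a raster."""
        return self.intersection(bounds)

    def expand(self, margin: float) -> "Box":
        return Box(
            self.x_min - margin, self.y_min - margin, self.x_max + margin, self.y_max + margin
        )

    def contains_point(self, x: float, y: float) -> bool:
        """Half-open membership test, consistent with pixel ownership."""
        return self.x_min <= x < self.x_max and self.y_min <= y < self.y_max

    @staticmethod
    def enclosing(boxes: Iterable["Box"]) -> "Box":
        """Minimum enclosing rectangle of a non-empty collection of boxes."""
        boxes = list(boxes)
        if not boxes:
            raise ValueError("enclosing() requires at least one box")
        return Box(
            min(b.x_min for b in boxes),
            min(b.y_min for b in boxes),
            max(b.x_max for b in boxes),
            max(b.y_max for b in boxes),
        )
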