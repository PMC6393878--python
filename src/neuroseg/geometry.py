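"""Parametric ellipses and rasterization helpers.

Coordinate convention (shared by every module): pixel coordinates are
(row, column), 0-based, row 0 at top. Rotation is measured in radians in
[0, pi) from the +column axis toward the +row axis.
"""
from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from .errors import ArgumentError

__all__ = ["EllipseParams", "ellipse_interior", "ellipse_perimeter"]


@dataclasses.dataclass(frozen=True)
class EllipseParams:
    """Parametric ellipse: center, semi-axes, rotation, accumulator support.

    Attributes
    ----------
    center_row, center_col : float
        Center in pixel coordinates.
    semi_major, semi_minor : float
        Semi-axis lengths in pixels; ``semi_major >= semi_minor > 0``.
    rotation : float
        Orientation of the major axis, radians in [0, pi).
    votes : float
        Accumulator support (0 for analytically constructed ellipses).
    """

    center_row: float
    center_col: float
    semi_major: float
    semi_minor: float
    rotation: float = 0.0
    votes: float = 0.0

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ArgumentError(
                f"require semi_major >= semi_minor > 0, got "
                f"({self.semi_major}, {self.semi_minor})"
            )
        object.__setattr__(self, "rotation", float(self.rotation) % math.pi)

    def shrunk(self, margin: float) -> "EllipseParams":
        """Ellipse with both semi-axes reduced by ``margin`` pixels."""
        return EllipseParams(
            self.center_row,
            self.center_col,
            self.semi_major - margin,
            self.semi_minor - margin,
            self.rotation,
            self.votes,
        )


def ellipse_interior(height: int, width: int, params: EllipseParams) -> np.ndarray:
    """Boolean mask of pixel centers inside the rotated ellipse (inclusive).

    A pixel (r, c) is interior iff its center satisfies
    ``(u/a)^2 + (v/b)^2 <= 1`` where (u, v) are its coordinates in the
    ellipse frame. Emits a warning if the mask comes out empty.
    """
    rows, cols = np.mgrid[0:height, 0:width]
    dy = rows - params.center_row
    dx = cols - params.center_col
    ct, st = math.cos(params.rotation), math.sin(params.rotation)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    mask = (u / params.semi_major) ** 2 + (v / params.semi_minor) ** 2 <= 1.0
    if not mask.any():
        warnings.warn("ellipse lies fully outside the image; mask is empty",
                      stacklevel=2)
    return mask


def ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's first approximation to the ellipse perimeter."""
    return math.pi * (3.0 * (a + b) - math.sqrt((3.0 * a + b) * (a + 3.0 * b)))
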