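"""Skull-outline detection and removal.

The bright skull ring is found by thresholding the slice, taking the outer
contour of the filled foreground, and voting over a deterministic grid of
ellipse parameters (center, semi-axes, rotation). The winning ellipse is
refined once on a finer grid; everything outside it (shrunk inward by a
margin) is zeroed to leave the cerebral-cortex slice for clustering.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import convex_hull_image

from .errors import ArgumentError, DetectionError, GeometryError
from .geometry import EllipseParams, ellipse_interior, ellipse_perimeter
from .image_io import GrayscaleSlice

__all__ = ["EllipseParams", "threshold_slice", "detect_skull_ellipse",
           "remove_skull", "estimate_band_thickness", "convex_hull_strip",
           "SUPPORT_FRACTION"]

log = logging.getLogger(__name__)

# Minimal accumulator support: this fraction of the ideal perimeter must vote.
SUPPORT_FRACTION = 0.30


def threshold_slice(s: GrayscaleSlice, method: str = "otsu",
                    level: Optional[float] = None) -> np.ndarray:
    """Binarize a (normalized) slice; foreground = pixels strictly above level.

    ``method='otsu'`` picks the between-class-variance-maximizing level;
    ``method='fixed'`` uses ``level`` verbatim.
    """
    if method == "otsu":
        px = s.pixels
        if np.ptp(px) == 0:
            return np.zeros_like(px, dtype=bool)
        level = float(threshold_otsu(px))
    elif method == "fixed":
        if level is None:
            raise ArgumentError("method 'fixed' requires a threshold level")
    else:
        raise ArgumentError(f"unknown threshold method {method!r}")
    return s.pixels > level


def _outer_contour(mask: np.ndarray) -> np.ndarray:
    """Outer edge pixels of the filled foreground (holes do not contribute).

    Only the largest connected blob votes, so isolated noise specks cannot
    skew the search ranges.
    """
    filled = ndimage.binary_fill_holes(mask)
    labeled, n = ndimage.label(filled, structure=np.ones((3, 3), dtype=bool))
    if n > 1:
        sizes = np.bincount(labeled.ravel())[1:]
        filled = labeled == (int(np.argmax(sizes)) + 1)
    eroded = ndimage.binary_erosion(filled, border_value=0)
    return filled & ~eroded


@dataclasses.dataclass(frozen=True)
class SearchRanges:
    """Deterministic Hough grid; any field left None is derived from the mask."""

    center_rows: Optional[np.ndarray] = None
    center_cols: Optional[np.ndarray] = None
    semi_major: Optional[np.ndarray] = None
    semi_minor: Optional[np.ndarray] = None
    rotations: Optional[np.ndarray] = None


def _default_ranges(edge_r: np.ndarray, edge_c: np.ndarray) -> SearchRanges:
    cr, cc = edge_r.mean(), edge_c.mean()
    half_r = (edge_r.max() - edge_r.min()) / 2.0
    half_c = (edge_c.max() - edge_c.min()) / 2.0
    big, small = max(half_r, half_c), min(half_r, half_c)
    a_grid = np.arange(max(4.0, big - 8.0), big + 8.1, 2.0)
    b_grid = np.arange(max(2.0, small - 8.0), small + 8.1, 2.0)
    return SearchRanges(
        center_rows=np.arange(cr - 4.0, cr + 4.1, 2.0),
        center_cols=np.arange(cc - 4.0, cc + 4.1, 2.0),
        semi_major=a_grid,
        semi_minor=b_grid,
        rotations=np.deg2rad(np.arange(0.0, 180.0, 10.0)),
    )


def _count_votes(edge_r, edge_c, cr, cc, theta, a_grid, b_grid, band):
    """Votes for all (a, b) pairs at one (center, rotation) cell.

    A vote is an edge pixel whose normalized radial deviation, scaled back to
    pixels by the minor axis, falls within ``band`` pixels of the ellipse.
    """
    dy = edge_r - cr
    dx = edge_c - cc
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    ua = (u[:, None] / a_grid) ** 2          # (E, A)
    vb = (v[:, None] / b_grid) ** 2          # (E, B)
    r = np.sqrt(ua[:, :, None] + vb[:, None, :])   # (E, A, B)
    scale = np.minimum(a_grid[:, None], b_grid[None, :])
    hits = np.abs(r - 1.0) * scale <= band
    return hits.sum(axis=0)                  # (A, B)


def _scan(edge_r, edge_c, ranges: SearchRanges, band: float):
    """Exhaustive vote count over the grid; returns (best_params, votes)."""
    best = (-1, None)
    for cr in ranges.center_rows:
        for cc in ranges.center_cols:
            for theta in ranges.rotations:
                votes = _count_votes(edge_r, edge_c, cr, cc, theta,
                                     ranges.semi_major, ranges.semi_minor, band)
                idx = int(np.argmax(votes))
                v = int(votes.flat[idx])
                if v > best[0]:
                    ai, bi = np.unravel_index(idx, votes.shape)
                    best = (v, (cr, cc, float(ranges.semi_major[ai]),
                                float(ranges.semi_minor[bi]), float(theta)))
    return best


def detect_skull_ellipse(mask: np.ndarray,
                         search: Optional[SearchRanges] = None) -> EllipseParams:
    """Fit the highest-vote ellipse to the outer contour of ``mask``.

    Coarse grid: rotation at 10 deg, axes and centers at 2 px; the best cell
    is refined once at 1 px / 2 deg resolution. Deterministic for a fixed
    grid. Raises :class:`DetectionError` when fewer than
    ``SUPPORT_FRACTION`` of the ideal perimeter votes.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DetectionError("cannot detect skull ellipse in an empty mask")
    contour = _outer_contour(mask)
    edge_r, edge_c = np.nonzero(contour)
    edge_r = edge_r.astype(np.float64)
    edge_c = edge_c.astype(np.float64)
    ranges = search if search is not None else _default_ranges(edge_r, edge_c)

    _, coarse = _scan(edge_r, edge_c, ranges, band=2.0)
    cr, cc, a, b, theta = coarse
    fine = SearchRanges(
        center_rows=np.arange(cr - 2.0, cr + 2.1, 1.0),
        center_cols=np.arange(cc - 2.0, cc + 2.1, 1.0),
        semi_major=np.arange(max(3.0, a - 2.0), a + 2.1, 1.0),
        semi_minor=np.arange(max(2.0, b - 2.0), b + 2.1, 1.0),
        rotations=theta + np.deg2rad(np.arange(-10.0, 10.1, 2.0)),
    )
    votes, refined = _scan(edge_r, edge_c, fine, band=1.5)
    cr, cc, a, b, theta = refined
    if a < b:
        a, b, theta = b, a, theta + math.pi / 2.0
    needed = SUPPORT_FRACTION * ellipse_perimeter(a, b)
    if votes < needed:
        raise DetectionError(
            f"best ellipse support {votes} below required {needed:.0f} votes")
    return EllipseParams(cr, cc, a, b, theta % math.pi, votes=float(votes))


def estimate_band_thickness(mask: np.ndarray, ellipse: EllipseParams) -> float:
    """Radial extent (px) of the bright outer band along the major axis.

    Walks inward from the detected outline along both major-axis directions,
    measuring the first consecutive run of foreground pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    ct, st = math.cos(ellipse.rotation), math.sin(ellipse.rotation)
    runs = []
    for sign in (+1.0, -1.0):
        run, started = 0, False
        for t in np.arange(ellipse.semi_major + 2.0, 0.0, -0.5):
            r = int(round(ellipse.center_row + sign * t * st))
            c = int(round(ellipse.center_col + sign * t * ct))
            inside = 0 <= r < h and 0 <= c < w
            fg = inside and mask[r, c]
            if fg:
                started = True
                run += 0.5
            elif started:
                break
        if started:
            runs.append(run)
    return float(np.mean(runs)) if runs else 0.0


def remove_skull(s: GrayscaleSlice, ellipse: EllipseParams,
                 margin: float) -> GrayscaleSlice:
    """Zero all pixels outside the ellipse shrunk inward by ``margin`` px."""
    if margin < 0:
        raise ArgumentError("margin must be >= 0")
    if margin >= ellipse.semi_minor:
        raise GeometryError(
            f"margin {margin} px >= semi-minor axis {ellipse.semi_minor} px")
    inside = ellipse_interior(s.height, s.width, ellipse.shrunk(margin))
    out = np.where(inside, s.pixels, 0.0)
    return GrayscaleSlice(out, s.source_format, s.intensity_max)


def convex_hull_strip(s: GrayscaleSlice, mask: np.ndarray,
                      margin: float) -> Tuple[GrayscaleSlice, np.ndarray]:
    """Fallback stripping: erode the convex hull of the foreground by margin."""
    hull = convex_hull_image(np.asarray(mask, dtype=bool))
    n = max(0, int(round(margin)))
    if n:
        hull = ndimage.binary_erosion(hull, iterations=n, border_value=0)
    log.warning("Hough detection unavailable; using convex-hull fallback "
                "(margin %.1f px)", margin)
    out = np.where(hull, s.pixels, 0.0)
    return GrayscaleSlice(out, s.source_format, s.intensity_max), hull
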