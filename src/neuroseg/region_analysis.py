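"""Connected-region postprocessing and the end-to-end segmentation pipelines.

``segment_gm_wm`` chains the full procedure: threshold → skull-ellipse
detection → removal → fuzzy c-means (c = 3) → tissue labeling → per-tissue
crisp masks → 8-connected component labeling → largest component → mask
overlay → boundary extraction. ``segment_tumor`` reuses the front end and
isolates the hyperintense cluster instead.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from . import clustering, skull_strip
from .errors import (ArgumentError, DetectionError, EmptyRegionError,
                     ShapeError)
from .geometry import EllipseParams, ellipse_interior
from .image_io import GrayscaleSlice, normalize_slice

__all__ = ["LabeledRegions", "SegmentationParams", "SegmentationResult",
           "TumorResult", "label_connected", "largest_component", "apply_mask",
           "extract_boundary", "segment_gm_wm", "segment_tumor"]

log = logging.getLogger(__name__)

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}

# Tumor candidates larger than this fraction of the brain area are implausible
# (the bright cluster caught white matter instead of a lesion).
TUMOR_MAX_BRAIN_FRACTION = 0.25


@dataclasses.dataclass
class LabeledRegions:
    """Connected-component partition of a binary mask.

    ``labels`` is 0 for background and 1..R for components, numbered by the
    raster-scan order of each component's first pixel; ``sizes[i]`` is the
    pixel count of component i+1.
    """

    labels: np.ndarray
    sizes: np.ndarray
    connectivity: int

    @property
    def count(self) -> int:
        return int(self.sizes.size)


def label_connected(mask: np.ndarray, connectivity: int = 8) -> LabeledRegions:
    """Label maximal connected foreground regions under 4- or 8-adjacency."""
    if connectivity not in _STRUCTURES:
        raise ArgumentError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask, dtype=bool)
    raw, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    # scipy already scans in raster order, but the contract is explicit:
    # renumber components by first-encountered pixel.
    labels = np.zeros_like(raw)
    if n:
        flat = raw.ravel()
        first = np.full(n + 1, flat.size, dtype=np.int64)
        nz = np.nonzero(flat)[0]
        np.minimum.at(first, flat[nz], nz)
        order = np.argsort(first[1:], kind="stable")  # old label-1 → rank
        remap = np.zeros(n + 1, dtype=raw.dtype)
        remap[1 + order] = np.arange(1, n + 1)
        labels = remap[raw]
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return LabeledRegions(labels=labels, sizes=sizes, connectivity=connectivity)


def largest_component(regions: LabeledRegions) -> np.ndarray:
    """Mask of the largest component; ties favor the earlier raster label."""
    if regions.count == 0:
        raise EmptyRegionError("no connected components to select from")
    best = int(np.argmax(regions.sizes)) + 1  # argmax → first max → earlier label
    return regions.labels == best


def apply_mask(s: GrayscaleSlice, mask: np.ndarray) -> GrayscaleSlice:
    """Keep original intensities on the mask, zero elsewhere."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != s.pixels.shape:
        raise ShapeError(
            f"mask shape {mask.shape} != slice shape {s.pixels.shape}")
    return GrayscaleSlice(np.where(mask, s.pixels, 0.0),
                          s.source_format, s.intensity_max)


def _boundary_mask(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with >= 1 background 4-neighbor (border = background)."""
    eroded = ndimage.binary_erosion(mask, structure=_STRUCTURES[4],
                                    border_value=0)
    return mask & ~eroded


_NEIGHBOR_STEPS = [(-1, 0), (-1, 1), (0, 1), (1, 1),
                   (1, 0), (1, -1), (0, -1), (-1, -1)]


def extract_boundary(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Boundary pixels in traversal order, one connected contour at a time.

    The boundary is the set of foreground pixels 4-adjacent to background
    (the image border counts as background); within each 8-connected contour
    pixels are ordered by a greedy neighbor walk from the first raster pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    boundary = _boundary_mask(mask)
    if not boundary.any():
        return []
    comps = label_connected(boundary, connectivity=8)
    out: List[Tuple[int, int]] = []
    for lbl in range(1, comps.count + 1):
        remaining = {(int(r), int(c))
                     for r, c in zip(*np.nonzero(comps.labels == lbl))}
        start = min(remaining)  # first raster pixel
        stack = [start]
        remaining.discard(start)
        while stack:
            r, c = stack.pop()
            out.append((r, c))
            for dr, dc in _NEIGHBOR_STEPS:
                nxt = (r + dr, c + dc)
                if nxt in remaining:
                    remaining.discard(nxt)
                    stack.append(nxt)
                    break
            else:
                # walk stuck: jump to the nearest remaining pixel of the contour
                if remaining:
                    nxt = min(remaining,
                              key=lambda p: (abs(p[0] - r) + abs(p[1] - c), p))
                    remaining.discard(nxt)
                    stack.append(nxt)
    return out


@dataclasses.dataclass
class SegmentationParams:
    """All tunables of the automatic pipeline (validated defaults)."""

    threshold_method: str = "otsu"
    threshold_level: Optional[float] = None
    strip_margin: Optional[float] = None  # None → 1.5 x estimated skull band
    clusters: int = 3
    fuzziness: float = 2.0
    tol: float = 1e-5
    max_iter: int = 100
    connectivity: int = 8
    engine: str = "fcm"
    seed: Optional[int] = None  # None → deterministic percentile init


@dataclasses.dataclass
class SegmentationResult:
    """Outputs of the GM/WM pipeline (masks, regions, boundaries, stripped)."""

    gm_mask: np.ndarray
    wm_mask: np.ndarray
    gm_region: GrayscaleSlice
    wm_region: GrayscaleSlice
    gm_boundary: List[Tuple[int, int]]
    wm_boundary: List[Tuple[int, int]]
    stripped: GrayscaleSlice
    brain_mask: np.ndarray
    ellipse: Optional[EllipseParams]
    used_fallback: bool
    model: clustering.ClusterModel
    stage_log: Dict[str, object]


@dataclasses.dataclass
class TumorResult:
    tumor_mask: np.ndarray
    tumor_region: GrayscaleSlice
    tumor_boundary: List[Tuple[int, int]]
    plausible: bool
    brain_area: int
    stripped: GrayscaleSlice
    stage_log: Dict[str, object]


def _strip(norm: GrayscaleSlice, params: SegmentationParams):
    """Threshold, detect the skull outline, remove it; returns the stripped
    slice, in-brain mask, ellipse (or None on fallback), and stage notes."""
    stage: Dict[str, object] = {}
    fg = skull_strip.threshold_slice(norm, params.threshold_method,
                                     params.threshold_level)
    if not fg.any():
        raise DetectionError("thresholded image is empty; nothing to segment")
    stage["foreground_px"] = int(fg.sum())
    try:
        ellipse = skull_strip.detect_skull_ellipse(fg)
        stage["ellipse"] = ellipse
        thickness = skull_strip.estimate_band_thickness(fg, ellipse)
        margin = (params.strip_margin if params.strip_margin is not None
                  else 1.5 * max(thickness, 1.0))
        stage["strip_margin_px"] = margin
        stripped = skull_strip.remove_skull(norm, ellipse, margin)
        brain = ellipse_interior(norm.height, norm.width,
                                 ellipse.shrunk(margin))
        return stripped, brain, ellipse, False, stage
    except DetectionError as exc:
        stage["detection_error"] = str(exc)
        margin = params.strip_margin if params.strip_margin is not None else 6.0
        stripped, brain = skull_strip.convex_hull_strip(norm, fg, margin)
        if not brain.any():
            raise DetectionError(
                f"skull stripping failed and fallback produced an empty "
                f"brain mask ({exc})") from exc
        return stripped, brain, None, True, stage


def _cluster_brain(stripped: GrayscaleSlice, brain: np.ndarray,
                   params: SegmentationParams) -> clustering.ClusterModel:
    coords = np.argwhere(brain)
    pixels = stripped.pixels[brain]
    rng = (np.random.default_rng(params.seed)
           if params.seed is not None else None)
    if params.engine == "kmeans":
        model = clustering.kmeans_cluster(pixels, params.clusters,
                                          tol=params.tol,
                                          max_iter=params.max_iter, rng=rng)
        model.coords = coords
        return model
    if params.engine == "fcm":
        return clustering.fcm_cluster(pixels, params.clusters,
                                      m=params.fuzziness, tol=params.tol,
                                      max_iter=params.max_iter, rng=rng,
                                      coords=coords)
    raise ArgumentError(f"unknown engine {params.engine!r}")


def _crisp_mask(model: clustering.ClusterModel, cluster: int,
                shape: Tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    sel = model.labels == cluster
    rc = model.coords[sel]
    mask[rc[:, 0], rc[:, 1]] = True
    return mask


def segment_gm_wm(s: GrayscaleSlice,
                  params: Optional[SegmentationParams] = None
                  ) -> SegmentationResult:
    """Fully automatic gray/white-matter segmentation of one slice."""
    params = params or SegmentationParams()
    norm = normalize_slice(s)
    stripped, brain, ellipse, fallback, stage = _strip(norm, params)

    model = _cluster_brain(stripped, brain, params)
    stage["iterations"] = len(model.objective_history)
    tissues = clustering.assign_tissue_labels(model, mode="gm_wm")
    by_tissue = {t: j for j, t in tissues.items()}
    shape = (s.height, s.width)
    gm_crisp = _crisp_mask(model, by_tissue["gm"], shape)
    wm_crisp = _crisp_mask(model, by_tissue["wm"], shape)
    assert not (gm_crisp & wm_crisp).any()  # argmax construction

    conn = params.connectivity
    gm_regions = label_connected(gm_crisp, conn)
    wm_regions = label_connected(wm_crisp, conn)
    stage["gm_components"] = gm_regions.count
    stage["wm_components"] = wm_regions.count
    gm_mask = largest_component(gm_regions)
    wm_mask = largest_component(wm_regions)

    return SegmentationResult(
        gm_mask=gm_mask,
        wm_mask=wm_mask,
        gm_region=apply_mask(s, gm_mask),
        wm_region=apply_mask(s, wm_mask),
        gm_boundary=extract_boundary(gm_mask),
        wm_boundary=extract_boundary(wm_mask),
        stripped=stripped,
        brain_mask=brain,
        ellipse=ellipse,
        used_fallback=fallback,
        model=model,
        stage_log=stage,
    )


def segment_tumor(s: GrayscaleSlice,
                  params: Optional[SegmentationParams] = None) -> TumorResult:
    """Isolate the hyperintense (tumor-candidate) region of one slice.

    Front end identical to the GM/WM pipeline; the brightest of the three
    tissue clusters is then re-clustered (c = 2) so the hyperintense lesion
    separates from normal white matter, and its largest connected component
    is returned. Candidates covering more than 25% of the brain area are
    flagged implausible (the bright cluster is white matter, not a lesion).
    """
    params = params or SegmentationParams()
    norm = normalize_slice(s)
    stripped, brain, ellipse, fallback, stage = _strip(norm, params)
    brain_area = int(brain.sum())

    model = _cluster_brain(stripped, brain, params)
    tissues = clustering.assign_tissue_labels(model, mode="tumor")
    bright = {t: j for j, t in tissues.items()}["tumor"]
    sel = model.labels == bright
    if not sel.any():
        raise EmptyRegionError("no pixels in the hyperintense cluster")
    sub = clustering.fcm_cluster(model.pixels[sel], c=2, m=params.fuzziness,
                                 tol=params.tol, max_iter=params.max_iter,
                                 coords=model.coords[sel])
    sub_bright = int(np.argmax(sub.centers))
    shape = (s.height, s.width)
    candidate = _crisp_mask(sub, sub_bright, shape)
    regions = label_connected(candidate, params.connectivity)
    # fill interior holes so the connected tumor region is solid
    tumor_mask = ndimage.binary_fill_holes(largest_component(regions))
    size = int(tumor_mask.sum())
    plausible = size <= TUMOR_MAX_BRAIN_FRACTION * brain_area
    if not plausible:
        log.warning("tumor candidate covers %.0f%% of the brain area; "
                    "flagged implausible", 100.0 * size / brain_area)
    stage.update({"ellipse": ellipse, "fallback": fallback,
                  "tumor_px": size, "brain_px": brain_area})
    return TumorResult(
        tumor_mask=tumor_mask,
        tumor_region=apply_mask(s, tumor_mask),
        tumor_boundary=extract_boundary(tumor_mask),
        plausible=plausible,
        brain_area=brain_area,
        stripped=stripped,
        stage_log=stage,
    )
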