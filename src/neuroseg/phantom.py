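"""Synthetic T1-like axial brain phantoms with exact ground-truth masks.

The phantom mimics the intensity ordering of a T1-weighted slice: a bright
elliptical skull ring, a dark CSF gap, an intermediate gray-matter annulus,
a bright white-matter core and, optionally, a hyperintense tumor blob.
Additive Gaussian noise (clipped to [0, 1]) models acquisition noise.
"""
from __future__ import annotations

import dataclasses
from typing import Dict, Optional, Tuple

import numpy as np

from .errors import GeometryError
from .geometry import EllipseParams, ellipse_interior
from .image_io import GrayscaleSlice, SourceFormat

__all__ = ["TumorSpec", "PhantomSpec", "GroundTruth", "make_ellipse_mask",
           "make_phantom", "default_spec"]

DEFAULT_INTENSITIES: Dict[str, float] = {
    "background": 0.00,
    "csf": 0.15,
    "gm": 0.45,
    "wm": 0.80,
    "skull": 0.95,
    "tumor": 0.90,
}


@dataclasses.dataclass(frozen=True)
class TumorSpec:
    center_row: float
    center_col: float
    radius: float
    enabled: bool = True


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one synthetic slice.

    Invariants: intensities ordered wm > gm > csf >= background; the nested
    rings must fit, i.e. ``skull.semi_minor - skull_thickness - csf_gap -
    gm_thickness >= 2``.
    """

    height: int = 256
    width: int = 256
    skull: EllipseParams = EllipseParams(128.0, 128.0, 110.0, 90.0, 0.0)
    skull_thickness: float = 6.0
    csf_gap: float = 8.0
    gm_thickness: float = 18.0
    intensities: Dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_INTENSITIES))
    noise_sigma: float = 0.0
    tumor: Optional[TumorSpec] = None
    seed: int = 0

    def validate(self) -> None:
        i = self.intensities
        if not (i["wm"] > i["gm"] > i["csf"] >= i["background"]):
            raise GeometryError(
                "intensities must satisfy wm > gm > csf >= background")
        inner = self.skull.semi_minor - (
            self.skull_thickness + self.csf_gap + self.gm_thickness)
        if inner < 2:
            raise GeometryError(
                f"infeasible nesting: inner semi-minor axis would be {inner:.1f} px")
        if self.noise_sigma < 0:
            raise GeometryError("noise_sigma must be >= 0")


@dataclasses.dataclass
class GroundTruth:
    """Exact tissue masks matching the generating geometry.

    Masks are pairwise disjoint; gm and wm each form one 8-connected
    component.
    """

    gm_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    skull_mask: np.ndarray
    tumor_mask: Optional[np.ndarray] = None

    def all_masks(self) -> Dict[str, np.ndarray]:
        out = {"gm": self.gm_mask, "wm": self.wm_mask,
               "csf": self.csf_mask, "skull": self.skull_mask}
        if self.tumor_mask is not None:
            out["tumor"] = self.tumor_mask
        return out


def make_ellipse_mask(height: int, width: int, params: EllipseParams) -> np.ndarray:
    """Rasterize the interior of a rotated ellipse as a boolean mask."""
    return ellipse_interior(height, width, params)


def default_spec(seed: int = 0, noise_sigma: float = 0.0,
                 tumor: bool = False) -> PhantomSpec:
    """Default 256x256 phantom; optional tumor blob in the WM core."""
    t = TumorSpec(center_row=118.0, center_col=146.0, radius=12.0) if tumor else None
    return PhantomSpec(noise_sigma=noise_sigma, tumor=t, seed=seed)


def make_phantom(spec: PhantomSpec) -> Tuple[GrayscaleSlice, GroundTruth]:
    """Render the phantom image and its exact ground truth.

    Deterministic given ``spec.seed``. With ``noise_sigma = 0`` the image is
    piecewise constant at the spec's tissue intensities.
    """
    spec.validate()
    h, w = spec.height, spec.width
    skull_outer = make_ellipse_mask(h, w, spec.skull)
    skull_inner = make_ellipse_mask(h, w, spec.skull.shrunk(spec.skull_thickness))
    csf_inner = make_ellipse_mask(
        h, w, spec.skull.shrunk(spec.skull_thickness + spec.csf_gap))
    gm_inner = make_ellipse_mask(
        h, w, spec.skull.shrunk(
            spec.skull_thickness + spec.csf_gap + spec.gm_thickness))

    skull_mask = skull_outer & ~skull_inner
    csf_mask = skull_inner & ~csf_inner
    gm_mask = csf_inner & ~gm_inner
    wm_mask = gm_inner.copy()

    tumor_mask: Optional[np.ndarray] = None
    if spec.tumor is not None and spec.tumor.enabled:
        t = spec.tumor
        blob = make_ellipse_mask(
            h, w, EllipseParams(t.center_row, t.center_col, t.radius, t.radius))
        tumor_mask = blob & wm_mask  # keep the blob inside the WM core
        wm_mask &= ~tumor_mask

    inten = spec.intensities
    img = np.full((h, w), inten["background"], dtype=np.float64)
    img[csf_mask] = inten["csf"]
    img[gm_mask] = inten["gm"]
    img[wm_mask] = inten["wm"]
    img[skull_mask] = inten["skull"]
    if tumor_mask is not None:
        img[tumor_mask] = inten["tumor"]

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    gt = GroundTruth(gm_mask=gm_mask, wm_mask=wm_mask, csf_mask=csf_mask,
                     skull_mask=skull_mask, tumor_mask=tumor_mask)
    return GrayscaleSlice(img, SourceFormat.ARRAY, 1.0), gt
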