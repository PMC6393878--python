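"""Read/write medical and raster images into the internal slice representation.

Supported formats: NIfTI-1 (.nii / .nii.gz), single-file DICOM (requires the
optional ``pydicom`` dependency), PNG, TIFF, JPEG. Volumetric inputs are
reduced to a single axial slice (default: the middle one); multi-channel
raster images are converted to luminance with an unweighted channel mean.
"""
from __future__ import annotations

import dataclasses
import enum
import os
from typing import Optional

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .errors import ArgumentError, BoundsError, FormatError, ShapeError

__all__ = ["SourceFormat", "GrayscaleSlice", "read_slice", "write_mask",
           "normalize_slice"]


class SourceFormat(enum.Enum):
    NIFTI = "nifti"
    DICOM = "dicom"
    PNG = "png"
    TIF = "tif"
    JPG = "jpg"
    ARRAY = "array"  # in-memory provenance (phantoms, intermediate stages)


_RASTER_EXT = {
    ".png": SourceFormat.PNG,
    ".tif": SourceFormat.TIF,
    ".tiff": SourceFormat.TIF,
    ".jpg": SourceFormat.JPG,
    ".jpeg": SourceFormat.JPG,
}

MIN_DIM = 16


@dataclasses.dataclass
class GrayscaleSlice:
    """A single 2-D intensity image with provenance metadata.

    Invariants: ``height, width >= 16``; all pixel values finite and >= 0.
    """

    pixels: np.ndarray
    source_format: SourceFormat = SourceFormat.ARRAY
    intensity_max: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ShapeError(f"slice must be 2-D, got shape {self.pixels.shape}")
        h, w = self.pixels.shape
        if h < MIN_DIM or w < MIN_DIM:
            raise ShapeError(f"slice must be at least {MIN_DIM}x{MIN_DIM}, got {h}x{w}")
        if not np.all(np.isfinite(self.pixels)):
            raise ArgumentError("slice contains non-finite pixel values")
        if np.any(self.pixels < 0):
            raise ArgumentError("slice contains negative pixel values")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _to_luminance(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:  # H x W x channels
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise FormatError(f"cannot reduce array of shape {arr.shape} to 2-D")
    return arr


def _native_max(arr: np.ndarray, dtype: np.dtype) -> float:
    if np.issubdtype(dtype, np.integer):
        return float(np.iinfo(dtype).max)
    return float(max(arr.max(initial=0.0), 1.0))


def _pick_slice(vol: np.ndarray, slice_index: Optional[int]) -> np.ndarray:
    if vol.ndim == 2:
        if slice_index not in (None, 0):
            raise BoundsError(f"slice_index {slice_index} out of range for 2-D image")
        return vol
    vol = vol.reshape(vol.shape[:3])  # drop trailing singleton dims
    n = vol.shape[2]
    idx = n // 2 if slice_index is None else slice_index
    if not 0 <= idx < n:
        raise BoundsError(f"slice_index {idx} out of range [0, {n})")
    return vol[:, :, idx]


def read_slice(path: str, slice_index: Optional[int] = None) -> GrayscaleSlice:
    """Read one axial 2-D slice from a medical or raster image file.

    For volumetric NIfTI (and multi-frame DICOM) inputs, ``slice_index``
    selects the axial plane; the default is the middle slice. Intensities
    are preserved at their native scale.
    """
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        try:
            img = nib.load(path)
            vol = np.asanyarray(img.dataobj, dtype=np.float64)
        except Exception as exc:  # pragma: no cover - defensive
            raise FormatError(f"unreadable NIfTI file {path}: {exc}") from exc
        arr = _pick_slice(vol, slice_index)
        return GrayscaleSlice(arr, SourceFormat.NIFTI,
                              _native_max(arr, img.get_data_dtype()))
    if lower.endswith(".dcm"):
        try:
            import pydicom
        except ImportError as exc:
            raise FormatError(
                "DICOM support requires the optional 'pydicom' dependency "
                "(pip install neuroseg[dicom])") from exc
        try:
            ds = pydicom.dcmread(path)
            arr = ds.pixel_array
        except Exception as exc:
            raise FormatError(f"unreadable DICOM file {path}: {exc}") from exc
        dtype = arr.dtype
        if arr.ndim == 3:
            arr = np.moveaxis(arr, 0, -1)  # frames last, like NIfTI axials
        arr = _pick_slice(np.asarray(arr, dtype=np.float64), slice_index)
        return GrayscaleSlice(arr, SourceFormat.DICOM, _native_max(arr, dtype))
    fmt = _RASTER_EXT.get(os.path.splitext(lower)[1])
    if fmt is None:
        raise FormatError(f"unsupported image format: {path}")
    try:
        raw = iio.imread(path)
    except Exception as exc:
        raise FormatError(f"unreadable {fmt.value} file {path}: {exc}") from exc
    dtype = raw.dtype
    arr = _to_luminance(np.asarray(raw, dtype=np.float64))
    if slice_index not in (None, 0):
        raise BoundsError("slice_index out of range for single-slice raster image")
    return GrayscaleSlice(arr, fmt, _native_max(arr, dtype))


def write_mask(mask: np.ndarray, path: str, format: Optional[str] = None) -> None:
    """Write a boolean mask as an image: foreground at maximal intensity, 0 off.

    ``read_slice(write_mask(m))`` thresholded at half range recovers ``m``
    exactly for PNG/TIFF/NIfTI.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or mask.shape[0] == 0 or mask.shape[1] == 0:
        raise ShapeError(f"mask must be a nonempty 2-D array, got {mask.shape}")
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).lower()
    if fmt in ("nii", "nii.gz", "nifti") or path.lower().endswith((".nii", ".nii.gz")):
        img = nib.Nifti1Image(mask.astype(np.uint8) * 255, affine=np.eye(4))
        nib.save(img, path)
        return
    if fmt in ("png", "tif", "tiff"):
        iio.imwrite(path, mask.astype(np.uint8) * 255)
        return
    raise FormatError(f"unsupported mask format: {fmt!r}")


def normalize_slice(s: GrayscaleSlice) -> GrayscaleSlice:
    """Affinely map intensities onto [0, 1]; a constant image maps to zeros.

    Idempotent on its own output and order-preserving.
    """
    lo = float(s.pixels.min())
    hi = float(s.pixels.max())
    if hi == lo:
        out = np.zeros_like(s.pixels)
    else:
        out = (s.pixels - lo) / (hi - lo)
    return GrayscaleSlice(out, s.source_format, 1.0)
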