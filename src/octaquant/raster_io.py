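"""Raster input/output and preprocessing for en-face OCTA images.

The pipeline works on 8-bit grayscale rasters with a known pixel scale
(pixels per mm).  Lesion delineation arrives either as an image whose
background outside the contour has been cleared to 0, or as an explicit
binary mask file of the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile


class RasterIOError(IOError):
    """Raised when an image file cannot be read or decoded."""


class ValidationError(ValueError):
    """Raised when an input violates a precondition (bad scale, empty ROI, ...)."""


@dataclass(frozen=True)
class RasterImage:
    """A 2D grayscale intensity grid with pixel-scale metadata.

    Parameters
    ----------
    pixels : ndarray
        2D array of intensities.  After :func:`to_8bit` all values lie in
        [0, 255] and the dtype is ``uint8``.
    scale : float
        Pixels per millimetre; strictly positive.  The study images are
        1024x1024 at 170 px/mm, i.e. ~6.02 mm across.
    """

    pixels: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValidationError(f"expected a 2D raster, got ndim={self.pixels.ndim}")
        if not (self.scale > 0):
            raise ValidationError(f"pixel scale must be positive, got {self.scale}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def physical_width_mm(self) -> float:
        """Physical width of the field of view in mm (width / scale)."""
        return self.width / self.scale


@dataclass(frozen=True)
class RoiMask:
    """Binary lesion-delineation mask; all biomarkers are restricted to it.

    ``provenance`` records whether the ROI came from the cleared-background
    convention ("derived-from-cleared-background") or from an explicit mask
    file ("explicit-mask-file").
    """

    mask: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        if self.mask.ndim != 2 or self.mask.dtype != bool:
            raise ValidationError("ROI mask must be a 2D boolean array")
        if not self.mask.any():
            raise ValidationError("empty ROI: mask contains no true pixel")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


def _collapse_channels(arr: np.ndarray) -> np.ndarray:
    """Reduce an (H, W, C) raster to one channel by an equal-weight mean.

    OCTA en-face exports are pseudo-gray, so any luminance weighting is
    equivalent on them; an alpha channel, if present, is dropped.
    """
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (2, 4):  # gray+alpha or RGBA
        arr = arr[:, :, :-1]
    if arr.ndim == 3:
        return arr.astype(np.float64).mean(axis=2)
    raise RasterIOError(f"cannot interpret array of shape {arr.shape} as a 2D image")


def load_image(path: str | Path, scale: float) -> RasterImage:
    """Read a TIFF or PNG raster and attach its pixel scale.

    Multi-channel inputs are collapsed to one grayscale channel.  Raises
    :class:`RasterIOError` naming the path on unreadable files and
    :class:`ValidationError` on non-positive scale.
    """
    path = Path(path)
    if not (scale > 0):
        raise ValidationError(f"pixel scale must be positive, got {scale}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - decoding errors vary by backend
        raise RasterIOError(f"cannot read image file {path}: {exc}") from exc
    arr = _collapse_channels(np.asarray(arr))
    return RasterImage(pixels=arr, scale=float(scale))


def save_image(image: RasterImage, path: str | Path) -> None:
    """Write an image as an 8-bit single-channel TIFF (or PNG by extension)."""
    path = Path(path)
    data = to_8bit(image).pixels if image.pixels.dtype != np.uint8 else image.pixels
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def to_8bit(image: RasterImage) -> RasterImage:
    """Linearly rescale the input's [min, max] range onto [0, 255].

    Values are rounded to nearest integer; a constant image maps to all
    zeros (the degenerate-range convention).  Idempotent on full-range
    8-bit inputs.
    """
    px = image.pixels.astype(np.float64)
    lo, hi = px.min(), px.max()
    if hi == lo:
        out = np.zeros(px.shape, dtype=np.uint8)
    else:
        out = np.rint((px - lo) * (255.0 / (hi - lo))).astype(np.uint8)
    return RasterImage(pixels=out, scale=image.scale)


def derive_roi(image: RasterImage, mask_path: str | Path | None = None) -> RoiMask:
    """Obtain the lesion ROI for an image.

    An explicit mask file (nonzero = inside) wins; otherwise the ROI is the
    set of nonzero pixels of the image, following the convention that the
    area outside the delineated contour has been cleared to 0.
    """
    if mask_path is not None:
        marr = _collapse_channels(np.asarray(iio.imread(Path(mask_path))))
        if marr.shape != image.pixels.shape:
            raise ValidationError(
                f"ROI mask shape {marr.shape} does not match image shape {image.pixels.shape}"
            )
        return RoiMask(mask=marr > 0, provenance="explicit-mask-file")
    mask = image.pixels > 0
    if not mask.any():
        raise ValidationError("empty ROI: image is all zero and no mask file was given")
    return RoiMask(mask=mask, provenance="derived-from-cleared-background")


def adjust_contrast(
    image: RasterImage,
    saturation_fraction: float = 0.0035,
    roi: RoiMask | None = None,
) -> RasterImage:
    """Percentile-based linear contrast stretch.

    Intensities at the ``saturation_fraction`` and ``1 - saturation_fraction``
    quantiles (of ROI pixels when a ROI is given, else of all pixels) map to
    0 and 255; values outside are clipped.  A degenerate range (all sampled
    pixels equal) passes the image through unchanged.
    """
    if not (0 <= saturation_fraction < 0.5):
        raise ValidationError(
            f"saturation_fraction must be in [0, 0.5), got {saturation_fraction}"
        )
    px = image.pixels.astype(np.float64)
    sample = px[roi.mask] if roi is not None else px.ravel()
    q_lo = float(np.quantile(sample, saturation_fraction))
    q_hi = float(np.quantile(sample, 1.0 - saturation_fraction))
    if q_hi <= q_lo:
        return image
    out = np.clip(np.rint((px - q_lo) * (255.0 / (q_hi - q_lo))), 0, 255).astype(np.uint8)
    return RasterImage(pixels=out, scale=image.scale)


def clear_outside(image: RasterImage, roi: RoiMask) -> RasterImage:
    """Set every pixel outside the ROI to 0."""
    if roi.mask.shape != image.pixels.shape:
        raise ValidationError("ROI shape does not match image shape")
    out = image.pixels.copy()
    out[~roi.mask] = 0
    return RasterImage(pixels=out, scale=image.scale)
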