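"""Filtering and binarization stages of the two-branch vessel pipeline.

Branch 1 denoises with a Gaussian kernel (1A), enhances tubular structures
with Hessian-based Frangi vesselness (1B) and binarizes with a local median
threshold (1C).  Branch 2 applies a Mexican-hat (Ricker wavelet) filter (2A)
before skeletonization.  All convolutions replicate edge values at the
border so the lesion boundary is not darkened artificially.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .raster_io import RasterImage, RoiMask, ValidationError


@dataclass(frozen=True)
class FilterConfig:
    """Tunable parameters of stages 1A-1C and 2A.

    Defaults follow the published operating point: Gaussian sigma 1 px,
    local-threshold window radius 8 px, Mexican-hat neighborhood radius
    13 px.  Frangi parameters follow the original vesselness conventions:
    beta = 0.5; c defaults to half the maximum Hessian Frobenius norm at
    each scale when left as None.
    """

    gaussian_sigma: float = 1.0
    threshold_radius: int = 8
    threshold_offset: float = 0.0
    mexican_hat_radius: int = 13
    mexican_hat_sigma: float | None = None  # None -> radius / 3
    frangi_scales: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0)
    frangi_beta: float = 0.5
    frangi_c: float | None = None

    def __post_init__(self) -> None:
        if not (self.gaussian_sigma > 0):
            raise ValidationError("gaussian_sigma must be positive")
        if self.threshold_radius < 1 or self.mexican_hat_radius < 1:
            raise ValidationError("window radii must be >= 1")
        if len(self.frangi_scales) == 0:
            raise ValidationError("frangi_scales must be non-empty")
        if any(s <= 0 for s in self.frangi_scales) or list(self.frangi_scales) != sorted(
            set(self.frangi_scales)
        ):
            raise ValidationError("frangi_scales must be positive and strictly increasing")


@dataclass(frozen=True)
class BinaryVesselMap:
    """Boolean vessel map (true = vessel) with pixel-scale metadata."""

    mask: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        if self.mask.ndim != 2 or self.mask.dtype != bool:
            raise ValidationError("vessel map must be a 2D boolean array")
        if not (self.scale > 0):
            raise ValidationError("pixel scale must be positive")


def _rescale_to_8bit(response: np.ndarray) -> np.ndarray:
    """Map a non-negative response onto [0, 255]; an all-zero response stays zero."""
    peak = response.max()
    if peak <= 0:
        return np.zeros(response.shape, dtype=np.uint8)
    return np.rint(response * (255.0 / peak)).astype(np.uint8)


def gaussian_blur(image: RasterImage, sigma: float = 1.0) -> RasterImage:
    """Stage 1A: convolve with the normalized 2D Gaussian kernel.

    G(x, y) = 1/(2 pi sigma^2) * exp(-(x^2 + y^2) / (2 sigma^2)); the kernel
    sums to one, so constants are preserved and no pixel over/undershoots the
    input range.  Output is re-quantized to 8-bit.
    """
    if not (sigma > 0):
        raise ValidationError(f"sigma must be positive, got {sigma}")
    smoothed = ndi.gaussian_filter(image.pixels.astype(np.float64), sigma, mode="nearest")
    out = np.clip(np.rint(smoothed), 0, 255).astype(np.uint8)
    return RasterImage(pixels=out, scale=image.scale)


def _hessian_eigenvalues(img: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Scale-normalized Hessian eigenvalues, ordered |lam1| <= |lam2|."""
    norm = sigma**2  # gamma-normalized derivatives
    h_rr = ndi.gaussian_filter(img, sigma, order=(2, 0), mode="nearest") * norm
    h_cc = ndi.gaussian_filter(img, sigma, order=(0, 2), mode="nearest") * norm
    h_rc = ndi.gaussian_filter(img, sigma, order=(1, 1), mode="nearest") * norm
    mean = 0.5 * (h_rr + h_cc)
    root = np.sqrt(((h_rr - h_cc) * 0.5) ** 2 + h_rc**2)
    mu1, mu2 = mean + root, mean - root  # mu1 >= mu2 numerically
    swap = np.abs(mu1) > np.abs(mu2)
    lam1 = np.where(swap, mu2, mu1)
    lam2 = np.where(swap, mu1, mu2)
    return lam1, lam2


def frangi_vesselness(
    image: RasterImage,
    scales: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0),
    beta: float = 0.5,
    c: float | None = None,
) -> RasterImage:
    """Stage 1B: Hessian-based vesselness for bright vessels on dark ground.

    Per pixel and scale, with eigenvalues |lam1| <= |lam2|:

        V = 0                                              if lam2 > 0
        V = exp(-R_B^2 / (2 beta^2)) (1 - exp(-S^2/(2 c^2)))  otherwise

    where R_B = lam1/lam2 (blobness) and S = sqrt(lam1^2 + lam2^2) (second
    order structure).  When ``c`` is None it is set per scale to half the
    maximum S over the image.  The final response is the maximum over
    scales, rescaled to 8-bit.  Invariant under adding a constant to the
    image (the Hessian is unaffected).
    """
    if len(scales) == 0:
        raise ValidationError("scale list must be non-empty")
    img = image.pixels.astype(np.float64)
    # remove the mean so truncated-kernel residue on flat regions is exactly
    # zero; the Hessian (hence the response) is unaffected by constant shifts
    img -= img.mean()
    best = np.zeros(img.shape, dtype=np.float64)
    for sigma in scales:
        lam1, lam2 = _hessian_eigenvalues(img, float(sigma))
        s2 = lam1**2 + lam2**2
        c_eff = c if c is not None else 0.5 * np.sqrt(s2.max())
        if c_eff <= 0:  # flat image at this scale: no structure anywhere
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            rb2 = np.where(lam2 != 0, (lam1 / np.where(lam2 != 0, lam2, 1.0)) ** 2, 0.0)
        v = np.exp(-rb2 / (2.0 * beta**2)) * (1.0 - np.exp(-s2 / (2.0 * c_eff**2)))
        v[lam2 >= 0] = 0.0  # bright-vessel convention: ridge needs lam2 < 0
        np.maximum(best, v, out=best)
    return RasterImage(pixels=_rescale_to_8bit(best), scale=image.scale)


def windowed_median(img: np.ndarray, radius: int) -> np.ndarray:
    """Median of the (2r+1)^2 window around each pixel, window clipped to bounds.

    Interior pixels (full windows) use a rank filter; the border band, where
    the window is clipped and may hold an even number of samples, is computed
    directly (even counts average the two middle values, as ``np.median``).
    """
    if radius < 1:
        raise ValidationError(f"radius must be >= 1, got {radius}")
    h, w = img.shape
    size = 2 * radius + 1
    med = np.empty((h, w), dtype=np.float64)
    if h >= size and w >= size:
        interior = ndi.median_filter(img, size=size, mode="nearest")
        med[radius : h - radius, radius : w - radius] = interior[
            radius : h - radius, radius : w - radius
        ]
        border: list[tuple[int, int]] = []
        for i in range(h):
            if radius <= i < h - radius:
                for j in list(range(radius)) + list(range(w - radius, w)):
                    border.append((i, j))
            else:
                border.extend((i, j) for j in range(w))
    else:
        border = [(i, j) for i in range(h) for j in range(w)]
    for i, j in border:
        win = img[max(0, i - radius) : i + radius + 1, max(0, j - radius) : j + radius + 1]
        med[i, j] = np.median(win)
    return med


def local_median_threshold(
    image: RasterImage,
    radius: int = 8,
    offset: float = 0.0,
    roi: RoiMask | None = None,
) -> BinaryVesselMap:
    """Stage 1C: local adaptive median thresholding.

    A pixel is vessel iff its value is strictly greater than the median of
    its (2r+1)x(2r+1) window (clipped to image bounds) minus ``offset``.
    Ties go to background.  Pixels outside the ROI are always background.
    """
    img = image.pixels
    med = windowed_median(img, radius)
    vessel = img.astype(np.float64) > (med - offset)
    if roi is not None:
        vessel &= roi.mask
    return BinaryVesselMap(mask=vessel, scale=image.scale)


def ricker_kernel(radius: int, sigma: float | None = None) -> np.ndarray:
    """Discrete 2D Ricker (Mexican-hat) kernel on a (2r+1)^2 grid.

    psi(x, y) = 1/(pi sigma^4) (1 - (x^2+y^2)/(2 sigma^2)) exp(-(x^2+y^2)/(2 sigma^2)),
    truncated to the neighborhood and re-centered to zero sum so constant
    regions give exactly zero response.  sigma defaults to radius/3 so the
    wavelet decays to near zero at the window edge.
    """
    if radius < 1:
        raise ValidationError(f"radius must be >= 1, got {radius}")
    s = float(sigma) if sigma is not None else radius / 3.0
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    r2 = ax[:, None] ** 2 + ax[None, :] ** 2
    k = (1.0 / (np.pi * s**4)) * (1.0 - r2 / (2.0 * s**2)) * np.exp(-r2 / (2.0 * s**2))
    return k - k.mean()


def mexican_hat(
    image: RasterImage, radius: int = 13, sigma: float | None = None
) -> RasterImage:
    """Stage 2A: convolve with the zero-mean 2D Ricker wavelet.

    Negative responses are clipped at 0 and the result is rescaled to 8-bit.
    The kernel is radially symmetric, so the response commutes with 90-degree
    rotations of a square image.
    """
    k = ricker_kernel(radius, sigma)
    resp = ndi.convolve(image.pixels.astype(np.float64), k, mode="nearest")
    resp = np.clip(resp, 0.0, None)
    return RasterImage(pixels=_rescale_to_8bit(resp), scale=image.scale)
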