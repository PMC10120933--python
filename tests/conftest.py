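import numpy as np
import pytest

from octaquant.raster_io import RasterImage, RoiMask
from octaquant.vessel_filters import BinaryVesselMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def raster(arr, scale=1.0):
    return RasterImage(pixels=np.asarray(arr), scale=scale)


def full_roi(shape):
    return RoiMask(mask=np.ones(shape, dtype=bool), provenance="explicit-mask-file")


def vessel_map(mask, scale=1.0):
    return BinaryVesselMap(mask=np.asarray(mask, dtype=bool), scale=scale)


def cross_raster(size=21):
    """A '+' of two perpendicular 1-px lines crossing at the center."""
    sk = np.zeros((size + 4, size + 4), dtype=bool)
    c = (size + 4) // 2
    half = size // 2
    sk[c, c - half : c + half + 1] = True
    sk[c - half : c + half + 1, c] = True
    return sk


def brute_force_windowed_median(img, radius):
    """Independent oracle: per-pixel np.median over the clipped window."""
    h, w = img.shape
    out = np.empty((h, w), dtype=np.float64)
    for i in range(h):
        for j in range(w):
            win = img[
                max(0, i - radius) : i + radius + 1, max(0, j - radius) : j + radius + 1
            ]
            out[i, j] = np.median(win)
    return out


def brute_force_box_count(mask, size):
    """Independent oracle: double-loop scan of the anchored s-by-s grid."""
    h, w = mask.shape
    count = 0
    for r0 in range(0, h, size):
        for c0 in range(0, w, size):
            if mask[r0 : r0 + size, c0 : c0 + size].any():
                count += 1
    return count
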