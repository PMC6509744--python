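"""sRGB to CIELAB conversion and Gaussian pre-filtering.

The detection pipeline works on the CIELAB b* opponent channel (blue
negative, yellow positive): green foliage and yellow-brown soil sit at
positive b*, dark blue-purple berries at low/negative b*, which is what
makes a histogram threshold on b* separate fruit from canopy.

The conversion implemented here is the CIE standard chain
sRGB (IEC 61966-2-1 transfer) -> linear RGB -> XYZ (D65) -> L*a*b*.
The reference white is taken as the XYZ image of unit linear RGB under
the same matrix, so every gray input maps *exactly* onto the neutral
axis (a* = b* = 0) instead of only approximately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "LabRaster",
    "ScalarChannel",
    "read_rgb_image",
    "srgb_to_lab",
    "extract_b_channel",
    "gaussian_smooth",
]

# sRGB -> XYZ (D65) matrix, IEC 61966-2-1 / ITU-R BT.709 primaries.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
# White point from the matrix itself: guarantees gray -> a* = b* = 0 exactly.
_WHITE = _SRGB_TO_XYZ @ np.ones(3)

_DELTA = 6.0 / 29.0


@dataclass(frozen=True)
class LabRaster:
    """Per-pixel CIELAB planes of one image. L in [0, 100]; b* is the
    blue(-)/yellow(+) opponent used for cluster segmentation."""

    L: np.ndarray
    a_star: np.ndarray
    b_star: np.ndarray

    @property
    def shape(self) -> tuple:
        return self.L.shape


@dataclass(frozen=True)
class ScalarChannel:
    """A single scalar plane (e.g. the b* channel), optionally smoothed."""

    values: np.ndarray
    name: str = "b*"
    smoothing_radius: Optional[float] = None


def read_rgb_image(path) -> np.ndarray:
    """Load an 8-bit RGB image (PNG/TIFF) as an H x W x 3 uint8 array."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    return arr


def _srgb_degamma(v: np.ndarray) -> np.ndarray:
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def _lab_f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3 * _DELTA**2) + 4.0 / 29.0)


def srgb_to_lab(image: np.ndarray) -> LabRaster:
    """Convert an 8-bit sRGB raster to CIELAB under D65.

    Parameters
    ----------
    image : (H, W, 3) array of uint8 (or integers in [0, 255])

    Returns
    -------
    LabRaster with float64 planes; neutral inputs (r=g=b) give a*=b*=0.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(
            f"expected an H x W x 3 RGB raster, got shape {arr.shape}"
        )
    if arr.dtype.kind not in "ui":
        raise ValueError("expected integer 8-bit channel values in [0, 255]")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("channel values must lie in [0, 255]")

    rgb = _srgb_degamma(arr.astype(np.float64) / 255.0)
    xyz = rgb @ _SRGB_TO_XYZ.T
    fxyz = _lab_f(xyz / _WHITE)
    fx, fy, fz = fxyz[..., 0], fxyz[..., 1], fxyz[..., 2]
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return LabRaster(L=L, a_star=a, b_star=b)


def extract_b_channel(lab: LabRaster) -> ScalarChannel:
    """Return the b* plane as a named scalar channel."""
    return ScalarChannel(values=lab.b_star.copy(), name="b*")


def gaussian_smooth(channel: ScalarChannel, radius: float = 2.0) -> ScalarChannel:
    """Gaussian low-pass with sigma = radius (pixels), reflective borders.

    Symmetric (half-sample reflect) border handling makes the filter
    mass-conserving: the channel mean is preserved to machine precision.
    """
    if radius <= 0:
        raise ValueError(f"smoothing radius must be positive, got {radius}")
    smoothed = ndimage.gaussian_filter(
        channel.values.astype(np.float64), sigma=float(radius), mode="reflect"
    )
    return ScalarChannel(values=smoothed, name=channel.name, smoothing_radius=float(radius))
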