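"""Region-of-interest extraction and contrast enhancement.

The raw near-infrared capture shows a bright finger on a dark background.
Preprocessing proceeds in four steps:

1. binarize at the Otsu threshold (between-class variance maximization),
2. take the centroid of the foreground object as the finger center,
3. crop a fixed 480 x 160 (width x height) window around that center,
4. downscale by 0.4 (bilinear) to 192 x 64 and apply a modified Gaussian
   high-pass mask to suppress the slowly varying finger profile and bring
   out the dark vein lines.

The high-pass mask is

    H(x, y) = a * (1 - exp(-D(x, y)^2 / (2 * D0^2))) + b

where ``D`` is the Euclidean distance from the mask center, ``a`` scales
the amplitude, ``b`` shifts the DC level and ``D0`` sets the Gaussian
width.  ``H`` equals ``b`` at the center and approaches ``a + b`` far from
it, i.e. low spatial frequencies are attenuated relative to high ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _skimage_resize

from .imaging import as_gray_image

__all__ = [
    "DegenerateImageError",
    "EmptyMaskError",
    "EnhancementParams",
    "otsu_threshold",
    "binarize",
    "object_centroid",
    "crop_roi",
    "resize",
    "build_highpass_mask",
    "enhance",
    "rescale_to_uint8",
    "preprocess_image",
]

ROI_WIDTH = 480
ROI_HEIGHT = 160
RESIZE_RATIO = 0.4


class DegenerateImageError(ValueError):
    """Image histogram cannot be split into two classes."""


class EmptyMaskError(ValueError):
    """Binary mask contains no foreground pixel."""


@dataclass(frozen=True)
class EnhancementParams:
    """Parameters of the modified Gaussian high-pass mask.

    S : odd mask side length in pixels (>= 3)
    a : amplitude adjustment (dimensionless)
    b : DC-level adjustment (dimensionless)
    D0 : Gaussian width in pixels; defaults to S / 2 when omitted, tying
        the filter's spatial scale to the mask extent
    """

    S: int = 15
    a: float = 12.53
    b: float = -4.0
    D0: float | None = None

    def __post_init__(self) -> None:
        if self.S < 3 or self.S % 2 == 0:
            raise ValueError(f"mask side S must be odd and >= 3, got {self.S}")
        if self.D0 is not None and self.D0 <= 0:
            raise ValueError(f"D0 must be positive, got {self.D0}")

    @property
    def d0(self) -> float:
        """Effective Gaussian width."""
        return self.S / 2.0 if self.D0 is None else float(self.D0)


def otsu_threshold(image: np.ndarray) -> int:
    """Otsu threshold level over the 256-bin histogram.

    Returns the level ``t`` that maximizes the between-class variance of
    the split ``{intensity < t}`` versus ``{intensity >= t}``.  Ties are
    broken toward the lowest level.

    Raises :class:`DegenerateImageError` for a constant image.
    """
    image = as_gray_image(image)
    hist = np.bincount(image.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError("constant image: histogram has a single class")
    p = hist / hist.sum()
    levels = np.arange(256, dtype=np.float64)
    # w0(t), mu0(t) for background {< t}; candidate t in 1..255
    w0 = np.cumsum(p)[:-1]           # cumulative up to level t-1
    m0 = np.cumsum(p * levels)[:-1]
    mu_total = float(np.sum(p * levels))
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * w0 - m0) ** 2 / (w0 * (1.0 - w0))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    return int(np.argmax(sigma_b)) + 1


def binarize(image: np.ndarray, level: int) -> np.ndarray:
    """Foreground mask: pixel is True iff its intensity is >= ``level``."""
    if not 0 <= level <= 255:
        raise ValueError(f"level must be in [0, 255], got {level}")
    return as_gray_image(image) >= level


def object_centroid(mask: np.ndarray) -> tuple[int, int]:
    """Rounded mean (row, col) of the True pixels, round-half-up.

    Raises :class:`EmptyMaskError` when no pixel is set.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise EmptyMaskError("no foreground object in mask")
    r = int(np.floor(rows.mean() + 0.5))
    c = int(np.floor(cols.mean() + 0.5))
    return (r, c)


def crop_roi(
    image: np.ndarray,
    center: tuple[int, int],
    roi_height: int = ROI_HEIGHT,
    roi_width: int = ROI_WIDTH,
) -> np.ndarray:
    """Fixed-size window centered on ``center`` (row, col).

    Near a border the window is shifted to lie fully inside the image, so
    every ROI pixel is real data.
    """
    image = as_gray_image(image)
    h, w = image.shape
    if h < roi_height or w < roi_width:
        raise ValueError(
            f"image {h}x{w} smaller than ROI {roi_height}x{roi_width}"
        )
    top = int(np.clip(center[0] - roi_height // 2, 0, h - roi_height))
    left = int(np.clip(center[1] - roi_width // 2, 0, w - roi_width))
    return image[top : top + roi_height, left : left + roi_width]


def resize(image: np.ndarray, ratio: float) -> np.ndarray:
    """Bilinear rescale by ``ratio``; output dims = round(dims * ratio)."""
    if ratio <= 0:
        raise ValueError(f"resize ratio must be positive, got {ratio}")
    image = as_gray_image(image)
    h, w = image.shape
    out_shape = (int(round(h * ratio)), int(round(w * ratio)))
    if out_shape[0] < 1 or out_shape[1] < 1:
        raise ValueError(f"ratio {ratio} collapses image to {out_shape}")
    if out_shape == (h, w):
        return image.copy()
    out = _skimage_resize(
        image.astype(np.float64),
        out_shape,
        order=1,
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def build_highpass_mask(params: EnhancementParams) -> np.ndarray:
    """S x S modified Gaussian high-pass mask.

    Weight at offset (x, y) from the center is
    ``a * (1 - exp(-(x^2 + y^2) / (2 * D0^2))) + b``; the center weight is
    exactly ``b`` and the far-field limit is ``a + b``.
    """
    s = params.S
    half = (s - 1) // 2
    offsets = np.arange(-half, half + 1, dtype=np.float64)
    d2 = offsets[:, None] ** 2 + offsets[None, :] ** 2
    return params.a * (1.0 - np.exp(-d2 / (2.0 * params.d0**2))) + params.b


def rescale_to_uint8(values: np.ndarray) -> np.ndarray:
    """Linear min-max rescale of a real array to [0, 255].

    A constant input maps to mid-gray 128 by convention.
    """
    values = np.asarray(values, dtype=np.float64)
    lo = values.min()
    hi = values.max()
    if hi == lo:
        return np.full(values.shape, 128, dtype=np.uint8)
    scaled = (values - lo) / (hi - lo) * 255.0
    return np.rint(scaled).astype(np.uint8)


def enhance(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Convolve with the high-pass mask (reflect padding) and rescale.

    Reflect padding avoids the dark-border artifacts that zero padding
    would imprint on the subsequent binary codes.  The real-valued result
    is min-max rescaled to an 8-bit image (constant output -> 128).
    """
    image = as_gray_image(image)
    mask = np.asarray(mask, dtype=np.float64)
    if mask.shape[0] > image.shape[0] or mask.shape[1] > image.shape[1]:
        raise ValueError(f"mask {mask.shape} larger than image {image.shape}")
    out = ndimage.convolve(image.astype(np.float64), mask, mode="reflect")
    return rescale_to_uint8(out)


def preprocess_image(
    image: np.ndarray,
    params: EnhancementParams | None = None,
    *,
    roi_height: int = ROI_HEIGHT,
    roi_width: int = ROI_WIDTH,
    ratio: float = RESIZE_RATIO,
) -> np.ndarray:
    """Full chain: Otsu -> centroid -> crop -> resize -> enhance.

    A 640 x 480 capture yields a 192 x 64 (width x height) enhanced image
    under the default ROI and ratio.
    """
    params = params or EnhancementParams()
    level = otsu_threshold(image)
    mask = binarize(image, level)
    center = object_centroid(mask)
    roi = crop_roi(image, center, roi_height=roi_height, roi_width=roi_width)
    small = resize(roi, ratio)
    return enhance(small, build_highpass_mask(params))
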