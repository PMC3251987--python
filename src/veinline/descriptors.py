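"""Binary texture descriptors: LLBP (line-shaped) and LBP (circular).

The local line binary pattern (LLBP) compares every pixel on a length-N
horizontal or vertical line against the line's center pixel through the
step function s(x) = 1 if x >= 0 else 0, yielding N-1 bits per pixel per
direction.  The line-shaped neighborhood tracks the elongated, curvilinear
vein structures better than the square LBP neighborhood.  The full LLBP
code concatenates the horizontal and vertical halves into 2(N-1) bits.

For a decimal reading of a single direction the two half-lines are
binomially weighted outward from the center,

    LLBP_h = sum_{n<c} s(h_n - h_c) 2^(c-n-1) + sum_{n>c} s(h_n - h_c) 2^(n-c-1),

and the LLBP magnitude is sqrt(LLBP_h^2 + LLBP_v^2).  Matching uses the
raw bit strings; the decimal values serve visualization and the magnitude
map.

Every descriptor trims the margin of pixels whose neighborhood would fall
outside the image: (N-1)/2 on all four sides for the LLBP family (which
co-registers the horizontal and vertical maps for concatenation), R for
LBP(P, R).
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imaging import as_gray_image

__all__ = [
    "CodeMap",
    "CodeGeometry",
    "step",
    "llbp_h",
    "llbp_v",
    "llbp_concat",
    "llbp",
    "llbp_magnitude",
    "lbp",
    "code_geometry",
    "code_to_grayscale",
    "save_codemap",
    "load_codemap",
]


def step(x):
    """Thresholding step: 1 for x >= 0, 0 for x < 0 (elementwise)."""
    return (np.asarray(x) >= 0).astype(np.uint8)


@dataclass
class CodeMap:
    """Per-pixel fixed-width binary codes over the valid interior region.

    ``bits`` has shape ``(valid_height, valid_width, bits_per_pixel)`` and
    dtype bool; bit k of a pixel is ``bits[r, c, k]``.  ``margin`` records
    the (top, bottom, left, right) trim relative to the source image.
    ``values`` is an optional per-pixel decimal reading used for
    visualization (None when a map was deserialized without it).
    """

    bits: np.ndarray
    margin: tuple[int, int, int, int]
    descriptor_tag: str
    values: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.bits.ndim != 3:
            raise ValueError(f"bits must be 3-D, got shape {self.bits.shape}")
        self.bits = self.bits.astype(bool, copy=False)

    @property
    def valid_height(self) -> int:
        return self.bits.shape[0]

    @property
    def valid_width(self) -> int:
        return self.bits.shape[1]

    @property
    def bits_per_pixel(self) -> int:
        return self.bits.shape[2]

    @property
    def total_bits(self) -> int:
        return self.bits.size

    def bitstream(self) -> np.ndarray:
        """Flat bit sequence (row-major, per-pixel bits contiguous)."""
        return self.bits.reshape(-1)

    def code_string(self, row: int, col: int) -> str:
        """Bit string of one pixel, e.g. ``'010111001111'``."""
        return "".join("1" if b else "0" for b in self.bits[row, col])


@dataclass(frozen=True)
class CodeGeometry:
    """Valid-region dimensions and code size of a descriptor on an image."""

    valid_height: int
    valid_width: int
    bits_per_pixel: int

    @property
    def total_bits(self) -> int:
        return self.valid_height * self.valid_width * self.bits_per_pixel


def _check_line(N: int) -> int:
    if N < 3 or N % 2 == 0:
        raise ValueError(f"line length N must be odd and >= 3, got {N}")
    return (N - 1) // 2  # margin; center position c = (N+1)/2 along the line


def _half_line_weights(m: int) -> np.ndarray:
    # weights in pixel order for offsets -m..-1, +1..+m
    left = 2 ** np.arange(m - 1, -1, -1, dtype=np.int64)
    right = 2 ** np.arange(0, m, dtype=np.int64)
    return np.concatenate([left, right])


def llbp_h(image: np.ndarray, N: int) -> CodeMap:
    """Horizontal LLBP component: (N-1)-bit codes, margin (N-1)/2.

    Bits are stored in pixel order along the line, left to right with the
    center excluded, so a constant image yields all-ones codes
    (s(0) = 1).
    """
    image = as_gray_image(image)
    m = _check_line(N)
    h, w = image.shape
    if w < N:
        raise ValueError(f"image width {w} < line length {N}")
    if h <= 2 * m or w <= 2 * m:
        raise ValueError(f"image {h}x{w} too small for margin {m}")
    signed = image.astype(np.int16)
    center = signed[m : h - m, m : w - m]
    vh, vw = center.shape
    offsets = [*range(-m, 0), *range(1, m + 1)]
    bits = np.empty((vh, vw, 2 * m), dtype=bool)
    for k, off in enumerate(offsets):
        bits[:, :, k] = signed[m : h - m, m + off : w - m + off] >= center
    values = bits.astype(np.int64) @ _half_line_weights(m)
    return CodeMap(bits, (m, m, m, m), "llbp_h", values=values)


def llbp_v(image: np.ndarray, N: int) -> CodeMap:
    """Vertical LLBP component; bits run top to bottom, center excluded.

    Equals the horizontal component of the transposed image, transposed
    back.
    """
    tmap = llbp_h(np.ascontiguousarray(as_gray_image(image).T), N)
    return CodeMap(
        np.ascontiguousarray(tmap.bits.transpose(1, 0, 2)),
        tmap.margin,
        "llbp_v",
        values=np.ascontiguousarray(tmap.values.T),
    )


def llbp_concat(h_map: CodeMap, v_map: CodeMap) -> CodeMap:
    """Full LLBP code: horizontal bits followed by vertical bits.

    The per-pixel width is 2(N-1); the stored decimal value is the LLBP
    magnitude sqrt(h^2 + v^2).
    """
    if h_map.descriptor_tag != "llbp_h" or v_map.descriptor_tag != "llbp_v":
        raise ValueError(
            f"expected (llbp_h, llbp_v), got "
            f"({h_map.descriptor_tag}, {v_map.descriptor_tag})"
        )
    if h_map.bits.shape != v_map.bits.shape or h_map.margin != v_map.margin:
        raise ValueError("geometry mismatch between horizontal and vertical maps")
    bits = np.concatenate([h_map.bits, v_map.bits], axis=2)
    values = None
    if h_map.values is not None and v_map.values is not None:
        values = np.hypot(h_map.values, v_map.values)
    return CodeMap(bits, h_map.margin, "llbp", values=values)


def llbp(image: np.ndarray, N: int) -> CodeMap:
    """Concatenated horizontal + vertical LLBP with 2(N-1) bits per pixel."""
    return llbp_concat(llbp_h(image, N), llbp_v(image, N))


def llbp_magnitude(h_value, v_value):
    """Magnitude of the two directional decimal values: sqrt(h^2 + v^2)."""
    return np.hypot(h_value, v_value)


def _sample_offsets(P: int, R: float) -> list[tuple[float, float]]:
    # first neighbor at angle 0 (to the right), counter-clockwise
    angles = 2.0 * np.pi * np.arange(P) / P
    return [(-R * np.sin(a), R * np.cos(a)) for a in angles]  # (drow, dcol)


def _bilinear_shift(image: np.ndarray, dy: float, dx: float, margin: int) -> np.ndarray:
    """Image sampled at (r + dy, c + dx) over the interior valid region."""
    h, w = image.shape
    eps = 1e-9
    y0 = int(np.floor(dy))
    x0 = int(np.floor(dx))
    fy = dy - y0
    fx = dx - x0
    if fy < eps:
        fy = 0.0
    elif fy > 1 - eps:
        y0, fy = y0 + 1, 0.0
    if fx < eps:
        fx = 0.0
    elif fx > 1 - eps:
        x0, fx = x0 + 1, 0.0
    rows = slice(margin, h - margin)
    cols = slice(margin, w - margin)

    def block(oy: int, ox: int) -> np.ndarray:
        return image[
            rows.start + y0 + oy : rows.stop + y0 + oy,
            cols.start + x0 + ox : cols.stop + x0 + ox,
        ]

    out = (1 - fy) * (1 - fx) * block(0, 0)
    if fx > 0:
        out = out + (1 - fy) * fx * block(0, 1)
    if fy > 0:
        out = out + fy * (1 - fx) * block(1, 0)
    if fy > 0 and fx > 0:
        out = out + fy * fx * block(1, 1)
    return out


def lbp(image: np.ndarray, P: int = 8, R: int = 1) -> CodeMap:
    """Local binary pattern with P circular samples at radius R.

    Neighbors at non-integer positions are bilinearly interpolated; each
    is compared to the center via the step function (>=).  Margin R on all
    sides.  Bit 0 is the sample at angle 0, proceeding counter-clockwise.
    """
    image = as_gray_image(image)
    if P < 1:
        raise ValueError(f"P must be >= 1, got {P}")
    if R < 1:
        raise ValueError(f"R must be >= 1, got {R}")
    h, w = image.shape
    if h <= 2 * R or w <= 2 * R:
        raise ValueError(f"image {h}x{w} too small for LBP radius {R}")
    imgf = image.astype(np.float64)
    center = imgf[R : h - R, R : w - R]
    bits = np.empty((h - 2 * R, w - 2 * R, P), dtype=bool)
    for k, (dy, dx) in enumerate(_sample_offsets(P, R)):
        bits[:, :, k] = _bilinear_shift(imgf, dy, dx, R) >= center
    weights = 2 ** np.arange(P - 1, -1, -1, dtype=np.int64)  # bit 0 is MSB
    values = bits.astype(np.int64) @ weights
    return CodeMap(bits, (R, R, R, R), "lbp", values=values)


def code_geometry(
    height: int,
    width: int,
    descriptor: str,
    *,
    N: int | None = None,
    P: int | None = None,
    R: int | None = None,
) -> CodeGeometry:
    """Closed-form valid-region dims and code size for a descriptor.

    For a 192-wide x 64-high enhanced image this reproduces the standard
    template sizes: LLBP N=21 -> 172 x 44 x 40 = 302,720 bits; vertical
    LLBP N=17 -> 176 x 48 x 16 = 135,168 bits; LBP(8,1) ->
    190 x 62 x 8 = 94,240 bits.
    """
    if descriptor in ("llbp", "llbp_h", "llbp_v"):
        if N is None:
            raise ValueError("LLBP descriptors require N")
        m = _check_line(N)
        vh, vw = height - 2 * m, width - 2 * m
        bpp = 2 * (N - 1) if descriptor == "llbp" else N - 1
    elif descriptor == "lbp":
        if P is None or R is None:
            raise ValueError("LBP requires P and R")
        vh, vw = height - 2 * R, width - 2 * R
        bpp = P
    else:
        raise ValueError(f"unknown descriptor {descriptor!r}")
    if vh < 1 or vw < 1:
        raise ValueError(
            f"descriptor {descriptor} does not fit a {height}x{width} image"
        )
    return CodeGeometry(vh, vw, bpp)


def compute_descriptor(
    image: np.ndarray,
    descriptor: str,
    *,
    N: int | None = None,
    P: int = 8,
    R: int = 1,
) -> CodeMap:
    """Dispatch by descriptor tag: llbp | llbp_h | llbp_v | lbp."""
    if descriptor == "llbp":
        return llbp(image, N)
    if descriptor == "llbp_h":
        return llbp_h(image, N)
    if descriptor == "llbp_v":
        return llbp_v(image, N)
    if descriptor == "lbp":
        return lbp(image, P=P, R=R)
    raise ValueError(f"unknown descriptor {descriptor!r}")


def code_to_grayscale(cmap: CodeMap) -> np.ndarray:
    """Render a code map as an 8-bit image for inspection.

    Uses the per-pixel decimal values, min-max normalized to [0, 255]
    (a constant map renders as uniform 128).
    """
    if cmap.values is None:
        raise ValueError("code map carries no decimal values to visualize")
    from .preprocess import rescale_to_uint8

    return rescale_to_uint8(cmap.values)


_MAGIC = b"VLCM"


def save_codemap(cmap: CodeMap, path: str | Path) -> None:
    """Serialize a code map as a packed bitstream template.

    Layout: 4-byte magic ``VLCM``, 4-byte big-endian header length, JSON
    header (descriptor tag, dims, bits per pixel, margin), then the bits
    of :meth:`CodeMap.bitstream` packed 8 per byte (big-endian bit order).
    Decimal values are not stored; they can be recomputed from the source
    image when needed.
    """
    header = json.dumps(
        {
            "descriptor": cmap.descriptor_tag,
            "valid_height": cmap.valid_height,
            "valid_width": cmap.valid_width,
            "bits_per_pixel": cmap.bits_per_pixel,
            "margin": list(cmap.margin),
        }
    ).encode()
    packed = np.packbits(cmap.bitstream())
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack(">I", len(header)))
        fh.write(header)
        fh.write(packed.tobytes())


def load_codemap(path: str | Path) -> CodeMap:
    """Inverse of :func:`save_codemap` (values are not restored)."""
    with open(path, "rb") as fh:
        if fh.read(4) != _MAGIC:
            raise ValueError(f"not a code map template: {path}")
        (hlen,) = struct.unpack(">I", fh.read(4))
        meta = json.loads(fh.read(hlen).decode())
        packed = np.frombuffer(fh.read(), dtype=np.uint8)
    n = meta["valid_height"] * meta["valid_width"] * meta["bits_per_pixel"]
    bits = np.unpackbits(packed, count=n).astype(bool)
    bits = bits.reshape(
        meta["valid_height"], meta["valid_width"], meta["bits_per_pixel"]
    )
    return CodeMap(bits, tuple(meta["margin"]), meta["descriptor"])
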