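"""Translation alignment by phase-only correlation (POC).

The POC surface of two equally sized images is the inverse Fourier
transform of their normalized cross-phase spectrum
``F * conj(G) / |F * conj(G)|``.  For a pure translation it is an impulse
at the shift, with peak height near 1; unrelated images give a flat
surface with a low peak.  Only the integer-pixel peak is used because the
downstream common-region crop operates on whole pixels.

A pair whose estimated shift exceeds the configured limits (default
|t_x| < 20, |t_y| < 10) is rejected outright — such displacement is
evidence the two images show different fingers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import as_gray_image

__all__ = [
    "TranslationEstimate",
    "AlignmentLimits",
    "apply_window",
    "poc_surface",
    "estimate_translation",
    "estimate_translation_from_spectra",
    "common_region",
]


@dataclass(frozen=True)
class TranslationEstimate:
    """Integer shift of image g relative to image f, plus POC peak height.

    ``g ~ f`` translated by ``(t_x, t_y)``: positive t_x moves content
    right (toward higher columns), positive t_y moves it down.
    """

    t_x: int
    t_y: int
    peak: float


@dataclass(frozen=True)
class AlignmentLimits:
    """Strict upper bounds on |t_x| and |t_y| for an acceptable pair."""

    max_tx: int = 20
    max_ty: int = 10

    def __post_init__(self) -> None:
        if self.max_tx <= 0 or self.max_ty <= 0:
            raise ValueError("alignment limits must be positive")


def apply_window(arr: np.ndarray, window: str | None) -> np.ndarray:
    """Optionally taper an image before its FFT ('none' or 'hann')."""
    if window in (None, "none"):
        return arr
    if window == "hann":
        h, w = arr.shape
        return arr * np.outer(np.hanning(h), np.hanning(w))
    raise ValueError(f"unknown window {window!r}")


_windowed = apply_window


def _surface_from_spectra(F: np.ndarray, G: np.ndarray) -> np.ndarray:
    cross = F * np.conj(G)
    mag = np.abs(cross)
    floor = np.finfo(np.float64).eps * max(mag.max(), 1.0) * cross.size
    safe = np.where(mag < floor, 1.0, mag)
    r = np.where(mag < floor, 0.0, cross) / safe
    return np.real(np.fft.ifft2(r))


def poc_surface(
    f: np.ndarray, g: np.ndarray, *, window: str | None = None
) -> np.ndarray:
    """Real part of the inverse FFT of the cross-phase spectrum.

    Spectral bins whose cross-power magnitude falls below a machine-eps
    scaled floor are treated as unit magnitude so they contribute nothing
    rather than amplifying numerical noise.
    """
    f = as_gray_image(f).astype(np.float64)
    g = as_gray_image(g).astype(np.float64)
    if f.shape != g.shape:
        raise ValueError(f"dimension mismatch: {f.shape} vs {g.shape}")
    F = np.fft.fft2(_windowed(f, window))
    G = np.fft.fft2(_windowed(g, window))
    return _surface_from_spectra(F, G)


def _wrap(index: int, size: int) -> int:
    """Map an FFT bin index to a signed shift in (-size/2, size/2]."""
    return index - size if index > size // 2 else index


def _estimate_from_surface(surface: np.ndarray) -> TranslationEstimate:
    h, w = surface.shape
    peak_idx = int(np.argmax(surface))
    py, px = divmod(peak_idx, w)
    # a shift of +d places the POC impulse at bin (-d) mod size
    t_y = _wrap((-py) % h, h)
    t_x = _wrap((-px) % w, w)
    return TranslationEstimate(t_x=t_x, t_y=t_y, peak=float(surface[py, px]))


def estimate_translation(
    f: np.ndarray, g: np.ndarray, *, window: str | None = None
) -> TranslationEstimate:
    """Shift of ``g`` relative to ``f`` from the POC peak location."""
    return _estimate_from_surface(poc_surface(f, g, window=window))


def estimate_translation_from_spectra(
    F: np.ndarray, G: np.ndarray
) -> TranslationEstimate:
    """As :func:`estimate_translation` from precomputed 2-D FFTs.

    Lets batch evaluation cache one forward FFT per image instead of two
    per pair.
    """
    if F.shape != G.shape:
        raise ValueError(f"dimension mismatch: {F.shape} vs {G.shape}")
    return _estimate_from_surface(_surface_from_spectra(F, G))


def common_region(
    f: np.ndarray,
    g: np.ndarray,
    t: TranslationEstimate,
    limits: AlignmentLimits = AlignmentLimits(),
) -> tuple[np.ndarray, np.ndarray] | None:
    """Overlapping windows of ``f`` and ``g`` under shift ``t``.

    Returns ``(f_c, g_c)`` of identical size ``(H - |t_y|) x (W - |t_x|)``
    when the shift is within limits, or ``None`` (rejection: the pair is
    deemed to show different fingers) otherwise.
    """
    f = as_gray_image(f)
    g = as_gray_image(g)
    if f.shape != g.shape:
        raise ValueError(f"dimension mismatch: {f.shape} vs {g.shape}")
    if abs(t.t_x) >= limits.max_tx or abs(t.t_y) >= limits.max_ty:
        return None
    h, w = f.shape
    ty, tx = t.t_y, t.t_x
    f_c = f[max(0, -ty) : h + min(0, -ty), max(0, -tx) : w + min(0, -tx)]
    g_c = g[max(0, ty) : h + min(0, ty), max(0, tx) : w + min(0, tx)]
    return f_c, g_c
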