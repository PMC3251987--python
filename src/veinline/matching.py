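"""Normalized Hamming-distance matching between binary vein templates.

Two equal-length bit streams are compared as

    HD = popcount(codeA XOR codeB) / CodeLength,

which is 0 for identical codes and 1 for complementary ones.  Genuine
pairs (same finger) cluster near 0; imposter pairs scatter around 0.5
since unrelated codes agree on about half their bits.

``verify_pair`` runs the full chain on two raw captures: preprocessing,
POC alignment, common-region crop, descriptor extraction on each common
region, then the Hamming distance.  Because the common regions shrink
with the shift magnitude, the code length varies per pair.  A pair whose
shift exceeds the alignment limits is scored with the maximal distance
1.0 and flagged rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import AlignmentLimits, TranslationEstimate, common_region, estimate_translation
from .config import PipelineConfig
from .descriptors import compute_descriptor
from .preprocess import preprocess_image

__all__ = ["MatchScore", "hamming_distance", "match_enhanced", "verify_pair"]


@dataclass(frozen=True)
class MatchScore:
    """Outcome of comparing two vein images."""

    hd: float
    rejected: bool
    translation: TranslationEstimate

    def __post_init__(self) -> None:
        if not 0.0 <= self.hd <= 1.0:
            raise ValueError(f"hd must lie in [0, 1], got {self.hd}")
        if self.rejected and self.hd != 1.0:
            raise ValueError("rejected pairs must score hd = 1.0")


def hamming_distance(codeA: np.ndarray, codeB: np.ndarray) -> float:
    """Fraction of differing bits between two equal-length bit streams."""
    a = np.asarray(codeA, dtype=bool).reshape(-1)
    b = np.asarray(codeB, dtype=bool).reshape(-1)
    if a.size != b.size:
        raise ValueError(f"code length mismatch: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("codes must contain at least one bit")
    return int(np.count_nonzero(a ^ b)) / a.size


def match_enhanced(
    enhA: np.ndarray, enhB: np.ndarray, config: PipelineConfig
) -> MatchScore:
    """Align two already enhanced images and score their templates."""
    t = estimate_translation(enhA, enhB, window=config.poc_window)
    limits = AlignmentLimits(max_tx=config.max_tx, max_ty=config.max_ty)
    regions = common_region(enhA, enhB, t, limits)
    if regions is None:
        return MatchScore(hd=1.0, rejected=True, translation=t)
    a_c, b_c = regions
    kwargs = dict(N=config.line_length, P=config.P, R=config.R)
    codeA = compute_descriptor(a_c, config.descriptor, **kwargs)
    codeB = compute_descriptor(b_c, config.descriptor, **kwargs)
    hd = hamming_distance(codeA.bitstream(), codeB.bitstream())
    return MatchScore(hd=hd, rejected=False, translation=t)


def verify_pair(
    imageA: np.ndarray, imageB: np.ndarray, config: PipelineConfig | None = None
) -> MatchScore:
    """End-to-end verification score between two raw captures."""
    config = config or PipelineConfig()
    enhA = preprocess_image(
        imageA,
        config.enhancement,
        roi_height=config.roi_height,
        roi_width=config.roi_width,
        ratio=config.resize_ratio,
    )
    enhB = preprocess_image(
        imageB,
        config.enhancement,
        roi_height=config.roi_height,
        roi_width=config.roi_width,
        ratio=config.resize_ratio,
    )
    return match_enhanced(enhA, enhB, config)
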