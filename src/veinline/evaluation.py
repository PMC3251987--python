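"""Verification-accuracy evaluation: FAR/FRR curves, EER, grid search.

Genuine pairs are all unordered pairs of images of the same finger;
imposter pairs are all remaining unordered cross-finger pairs.  A probe
is accepted at threshold t when its Hamming distance satisfies hd <= t,
so the false-acceptance rate FAR(t) (imposters accepted) is
non-decreasing in t and the false-rejection rate FRR(t) (genuine pairs
rejected) is non-increasing.  The equal error rate (EER) is the common
value where the two curves cross, found by linear interpolation between
the adjacent grid thresholds that bracket the sign change of FAR - FRR.

The parameter grid search mirrors the usual tuning protocol: for each
(line length N, mask size S) cell the full pipeline is re-run on every
pair of a tuning subset and the cell's EER recorded; the argmin cell is
the chosen operating point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .align import (
    AlignmentLimits,
    apply_window,
    common_region,
    estimate_translation_from_spectra,
)
from .config import PipelineConfig
from .descriptors import compute_descriptor
from .imaging import DatasetIndex, load_image
from .matching import hamming_distance
from .preprocess import preprocess_image

__all__ = [
    "ScoreSet",
    "VerificationReport",
    "GridSearchResult",
    "enumerate_pairs",
    "far_frr_curves",
    "equal_error_rate",
    "verification_report",
    "score_images",
    "score_dataset",
    "grid_search",
]


class PairingError(ValueError):
    """Dataset admits no genuine pairs."""


@dataclass
class ScoreSet:
    """Labeled Hamming distances for genuine and imposter comparisons."""

    genuine: np.ndarray
    imposter: np.ndarray

    def __post_init__(self) -> None:
        self.genuine = np.asarray(self.genuine, dtype=np.float64).reshape(-1)
        self.imposter = np.asarray(self.imposter, dtype=np.float64).reshape(-1)
        for name, arr in (("genuine", self.genuine), ("imposter", self.imposter)):
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ValueError(f"{name} scores must lie in [0, 1]")


@dataclass
class VerificationReport:
    """FAR/FRR curves over a threshold grid, with the EER operating point.

    Rates are percentages in [0, 100].
    """

    thresholds: np.ndarray
    far: np.ndarray
    frr: np.ndarray
    eer: float | None = None
    eer_threshold: float | None = None


@dataclass
class GridSearchResult:
    """EER(%) table over the (N, S) parameter grid."""

    N_values: list[int]
    S_values: list[int]
    eer_table: np.ndarray  # shape (len(N_values), len(S_values)); NaN = failed cell
    errors: dict[tuple[int, int], str] = field(default_factory=dict)

    @property
    def best(self) -> tuple[int, int, float]:
        """(N, S, EER) of the argmin cell."""
        if np.all(np.isnan(self.eer_table)):
            raise ValueError("every grid cell failed")
        i, j = np.unravel_index(np.nanargmin(self.eer_table), self.eer_table.shape)
        return (self.N_values[i], self.S_values[j], float(self.eer_table[i, j]))


def enumerate_pairs(index: DatasetIndex) -> tuple[np.ndarray, np.ndarray]:
    """All unordered image pairs, split into genuine and imposter.

    Returns two integer arrays of shape (n_pairs, 2) holding entry
    indices into ``index``.  With F fingers of k_f images each, the
    genuine count is sum_f C(k_f, 2) and the imposter count
    C(sum_f k_f, 2) minus that; e.g. 204 fingers x 10 images give
    9,180 genuine and 2,070,600 imposter pairs.
    """
    n = len(index)
    if n < 2:
        raise PairingError("need at least two images to form pairs")
    fingers = index.finger_ids()
    fid = {f: i for i, f in enumerate(fingers)}
    labels = np.fromiter(
        (fid[e.finger_id] for e in index.entries), dtype=np.int64, count=n
    )
    i_idx, j_idx = np.triu_indices(n, k=1)
    same = labels[i_idx] == labels[j_idx]
    if not np.any(same):
        raise PairingError("no finger has two or more samples: no genuine pairs")
    genuine = np.stack([i_idx[same], j_idx[same]], axis=1)
    imposter = np.stack([i_idx[~same], j_idx[~same]], axis=1)
    return genuine, imposter


def far_frr_curves(scores: ScoreSet, n_thresholds: int = 1001) -> VerificationReport:
    """FAR(t) and FRR(t) in percent over an even grid of t in [0, 1]."""
    if scores.genuine.size == 0 or scores.imposter.size == 0:
        raise ValueError("both genuine and imposter score lists must be non-empty")
    thresholds = np.linspace(0.0, 1.0, n_thresholds)
    gen = np.sort(scores.genuine)
    imp = np.sort(scores.imposter)
    # accept iff hd <= t
    far = np.searchsorted(imp, thresholds, side="right") / imp.size * 100.0
    frr = (gen.size - np.searchsorted(gen, thresholds, side="right")) / gen.size * 100.0
    return VerificationReport(thresholds=thresholds, far=far, frr=frr)


def equal_error_rate(report: VerificationReport) -> float:
    """EER(%) at the FAR/FRR crossing, linearly interpolated.

    Fills ``report.eer`` and ``report.eer_threshold`` and returns the
    EER.  If the curves never cross inside the grid, the boundary value
    is returned with a warning.
    """
    d = report.far - report.frr
    idx = np.nonzero(d >= 0)[0]
    if idx.size == 0:  # FAR stays below FRR everywhere
        warnings.warn("FAR/FRR curves do not cross within the threshold grid")
        i = len(d) - 1
        report.eer = float((report.far[i] + report.frr[i]) / 2.0)
        report.eer_threshold = float(report.thresholds[i])
        return report.eer
    i = int(idx[0])
    if i == 0 or d[i] == 0.0:
        report.eer = float(report.far[i])
        report.eer_threshold = float(report.thresholds[i])
        return report.eer
    # interpolate between grid points i-1 (d<0) and i (d>0)
    alpha = -d[i - 1] / (d[i] - d[i - 1])
    report.eer = float(report.far[i - 1] + alpha * (report.far[i] - report.far[i - 1]))
    report.eer_threshold = float(
        report.thresholds[i - 1]
        + alpha * (report.thresholds[i] - report.thresholds[i - 1])
    )
    return report.eer


def verification_report(scores: ScoreSet, n_thresholds: int = 1001) -> VerificationReport:
    """Curves plus EER in one call."""
    report = far_frr_curves(scores, n_thresholds)
    equal_error_rate(report)
    return report


def score_images(
    images: list[np.ndarray],
    genuine: np.ndarray,
    imposter: np.ndarray,
    config: PipelineConfig,
    *,
    preprocessed: bool = False,
) -> ScoreSet:
    """Hamming scores for listed pairs of raw (or pre-enhanced) images.

    Each image is preprocessed once and its FFT cached, so per-pair work
    reduces to one inverse FFT for the alignment plus the descriptor on
    the common regions.
    """
    if preprocessed:
        enhanced = [np.asarray(im) for im in images]
    else:
        enhanced = [
            preprocess_image(
                im,
                config.enhancement,
                roi_height=config.roi_height,
                roi_width=config.roi_width,
                ratio=config.resize_ratio,
            )
            for im in images
        ]
    limits = AlignmentLimits(max_tx=config.max_tx, max_ty=config.max_ty)
    kwargs = dict(N=config.line_length, P=config.P, R=config.R)
    spectra = [
        np.fft.fft2(apply_window(im.astype(np.float64), config.poc_window))
        for im in enhanced
    ]

    def pair_score(i: int, j: int) -> float:
        a, b = enhanced[i], enhanced[j]
        t = estimate_translation_from_spectra(spectra[i], spectra[j])
        regions = common_region(a, b, t, limits)
        if regions is None:
            return 1.0
        codeA = compute_descriptor(regions[0], config.descriptor, **kwargs)
        codeB = compute_descriptor(regions[1], config.descriptor, **kwargs)
        return hamming_distance(codeA.bitstream(), codeB.bitstream())

    gen_scores = np.array([pair_score(i, j) for i, j in genuine], dtype=np.float64)
    imp_scores = np.array([pair_score(i, j) for i, j in imposter], dtype=np.float64)
    return ScoreSet(genuine=gen_scores, imposter=imp_scores)


def score_dataset(index: DatasetIndex, config: PipelineConfig) -> ScoreSet:
    """Enumerate all pairs of a dataset and score them end to end."""
    genuine, imposter = enumerate_pairs(index)
    images = [load_image(e.path) for e in index.entries]
    return score_images(images, genuine, imposter, config)


def grid_search(
    index: DatasetIndex,
    N_values: list[int],
    S_values: list[int],
    config: PipelineConfig | None = None,
) -> GridSearchResult:
    """EER(%) of the full pipeline for every (N, S) cell.

    Cells are independent: a failing cell is recorded as NaN with its
    error message and the rest of the grid still completes.  Raw images
    are loaded once; preprocessing is redone per S and scoring per N.
    """
    config = config or PipelineConfig()
    genuine, imposter = enumerate_pairs(index)
    raw = [load_image(e.path) for e in index.entries]
    table = np.full((len(N_values), len(S_values)), np.nan)
    errors: dict[tuple[int, int], str] = {}
    for j, S in enumerate(S_values):
        try:
            cfg_s = config.with_params(S=S)
            enhanced = [
                preprocess_image(
                    im,
                    cfg_s.enhancement,
                    roi_height=cfg_s.roi_height,
                    roi_width=cfg_s.roi_width,
                    ratio=cfg_s.resize_ratio,
                )
                for im in raw
            ]
        except Exception as exc:  # whole column unusable
            for N in N_values:
                errors[(N, S)] = str(exc)
            continue
        for i, N in enumerate(N_values):
            try:
                cfg = cfg_s.with_params(N=N)
                scores = score_images(
                    enhanced, genuine, imposter, cfg, preprocessed=True
                )
                table[i, j] = verification_report(
                    scores, config.n_thresholds
                ).eer
            except Exception as exc:
                errors[(N, S)] = str(exc)
    return GridSearchResult(
        N_values=list(N_values), S_values=list(S_values), eer_table=table, errors=errors
    )
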