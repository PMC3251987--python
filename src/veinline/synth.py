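"""Deterministic synthetic finger-vein image generator.

Emulates the structure of a near-infrared finger-vein capture: a bright
finger-shaped band on a dark background, crossed by dark, smooth,
mostly longitudinal vein curves.  Each *finger* is a fixed random model
(vein spline control points, widths and depths, finger outline); each
*sample* of that finger re-renders the model with translation jitter, a
global brightness offset, optical blur and sensor noise — the nuisance
factors the preprocessing and alignment stages exist to absorb.

Everything is a pure function of integer seeds: the same
``(finger_seed, sample_seed)`` always yields a bit-identical image, and
a whole dataset is a pure function of its root seed and counts.

What the generator does *not* model: skin scattering, depth-dependent
vein contrast, illumination gradients from LED geometry, or finger
rotation (the capture device physically constrains rotation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .imaging import (
    FINGER_LABELS,
    DatasetIndex,
    IndexEntry,
    save_dataset_index,
    save_image,
)

__all__ = [
    "IMAGE_HEIGHT",
    "IMAGE_WIDTH",
    "CaptureParams",
    "FingerModel",
    "make_finger_model",
    "generate_finger_image",
    "dataset_layout",
    "generate_dataset",
]

IMAGE_HEIGHT = 480
IMAGE_WIDTH = 640

_BACKGROUND = 25.0
_FINGER_LEVEL = 175.0


@dataclass(frozen=True)
class CaptureParams:
    """Per-sample nuisance magnitudes.

    jitter_tx / jitter_ty : max |translation| per sample, pixels at
        capture scale; defaults stay within the downstream alignment
        limits so genuine pairs remain alignable
    brightness_sd : s.d. of the per-sample global intensity offset
    noise_sd : s.d. of additive per-pixel Gaussian sensor noise
    blur_sigma : optical blur, pixels
    """

    jitter_tx: int = 8
    jitter_ty: int = 4
    brightness_sd: float = 8.0
    noise_sd: float = 6.0
    blur_sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.jitter_tx < 0 or self.jitter_ty < 0:
            raise ValueError("jitter bounds must be non-negative")
        if self.brightness_sd < 0 or self.noise_sd < 0 or self.blur_sigma < 0:
            raise ValueError("noise magnitudes must be non-negative")


@dataclass
class FingerModel:
    """Stable anatomy of one synthetic finger."""

    finger_seed: int
    center_row: float
    half_height: float
    half_width: float
    vein_rows: list[np.ndarray] = field(default_factory=list)  # control rows
    vein_cols: list[np.ndarray] = field(default_factory=list)  # control cols
    vein_widths: list[float] = field(default_factory=list)
    vein_depths: list[float] = field(default_factory=list)


def make_finger_model(finger_seed: int) -> FingerModel:
    """Draw a finger model from its seed.

    Veins are random cubic splines through 4-7 control points spanning
    the finger lengthwise, with widths 3-8 px and intensity depths
    40-70 at capture scale; control points are kept inside the central
    band of the finger outline.
    """
    rng = np.random.default_rng(finger_seed)
    center_row = IMAGE_HEIGHT / 2 + rng.uniform(-12, 12)
    half_height = rng.uniform(95, 115)
    half_width = rng.uniform(290, 315)
    n_veins = int(rng.integers(3, 8))
    model = FingerModel(
        finger_seed=finger_seed,
        center_row=center_row,
        half_height=half_height,
        half_width=half_width,
    )
    for _ in range(n_veins):
        n_ctrl = int(rng.integers(4, 8))
        cols = np.sort(
            rng.uniform(
                IMAGE_WIDTH / 2 - half_width * 0.95,
                IMAGE_WIDTH / 2 + half_width * 0.95,
                size=n_ctrl,
            )
        )
        # enforce strictly increasing knots for the spline
        cols = cols + np.arange(n_ctrl) * 1e-3
        base = center_row + rng.uniform(-0.7, 0.7) * half_height
        rows = base + np.cumsum(rng.normal(0.0, 12.0, size=n_ctrl))
        rows = np.clip(
            rows,
            center_row - 0.8 * half_height,
            center_row + 0.8 * half_height,
        )
        model.vein_rows.append(rows)
        model.vein_cols.append(cols)
        model.vein_widths.append(float(rng.uniform(3.0, 8.0)))
        model.vein_depths.append(float(rng.uniform(40.0, 70.0)))
    return model


def _finger_profile(model: FingerModel, dy: int, dx: int) -> np.ndarray:
    """Bright superellipse band with a smooth lateral intensity falloff."""
    rows = np.arange(IMAGE_HEIGHT, dtype=np.float64)[:, None]
    cols = np.arange(IMAGE_WIDTH, dtype=np.float64)[None, :]
    cy = model.center_row + dy
    cx = IMAGE_WIDTH / 2 + dx
    u = (rows - cy) / model.half_height
    v = (cols - cx) / model.half_width
    inside = u**4 + v**4 <= 1.0
    # thicker tissue at the finger axis transmits less IR -> brighter edges
    shading = np.broadcast_to(1.0 - 0.25 * u**2, inside.shape)
    return np.where(inside, _FINGER_LEVEL * shading, _BACKGROUND)


def _render_veins(model: FingerModel, dy: int, dx: int) -> np.ndarray:
    """Dark-vein layer: splines splatted and Gaussian-widened."""
    layer = np.zeros((IMAGE_HEIGHT, IMAGE_WIDTH))
    for rows, cols, width, depth in zip(
        model.vein_rows, model.vein_cols, model.vein_widths, model.vein_depths
    ):
        spline = CubicSpline(cols, rows)
        length = cols[-1] - cols[0]
        t = np.linspace(cols[0], cols[-1], max(int(length * 4), 32))
        rr = np.rint(spline(t) + dy).astype(np.int64)
        cc = np.rint(t + dx).astype(np.int64)
        keep = (rr >= 0) & (rr < IMAGE_HEIGHT) & (cc >= 0) & (cc < IMAGE_WIDTH)
        impulses = np.zeros((IMAGE_HEIGHT, IMAGE_WIDTH))
        np.add.at(impulses, (rr[keep], cc[keep]), 1.0)
        blurred = ndimage.gaussian_filter(impulses, sigma=width / 2.2)
        peak = blurred.max()
        if peak > 0:
            layer += blurred * (depth / peak)
    return layer


def generate_finger_image(
    model: FingerModel,
    sample_seed: int,
    params: CaptureParams = CaptureParams(),
) -> np.ndarray:
    """Render one 640 x 480 8-bit sample of a finger.

    Fully determined by ``(model.finger_seed, sample_seed, params)``.
    With zero jitter and zero noise magnitudes, every sample of a finger
    is identical.
    """
    rng = np.random.default_rng([model.finger_seed, sample_seed])
    dx = int(rng.integers(-params.jitter_tx, params.jitter_tx + 1))
    dy = int(rng.integers(-params.jitter_ty, params.jitter_ty + 1))
    brightness = rng.normal(0.0, params.brightness_sd) if params.brightness_sd else 0.0

    scene = _finger_profile(model, dy, dx) - _render_veins(model, dy, dx)
    if params.blur_sigma > 0:
        scene = ndimage.gaussian_filter(scene, sigma=params.blur_sigma)
    scene = scene + brightness
    if params.noise_sd > 0:
        scene = scene + rng.normal(0.0, params.noise_sd, size=scene.shape)
    return np.clip(np.rint(scene), 0, 255).astype(np.uint8)


def _finger_seed(root_seed: int, finger_index: int) -> int:
    # stable per-finger seed below 2**31, decoupled across root seeds
    return int(
        np.random.SeedSequence([root_seed, finger_index]).generate_state(1)[0]
        % (2**31)
    )


def dataset_layout(
    n_subjects: int,
    fingers_per_subject: int,
    samples_per_finger: int,
    root: str | Path = ".",
    fmt: str = "png",
) -> DatasetIndex:
    """Index skeleton for a subjects x fingers x samples dataset.

    No images are written; entry count is the product of the three
    counts (e.g. 51 x 4 x 10 = 2040).
    """
    if min(n_subjects, fingers_per_subject, samples_per_finger) < 1:
        raise ValueError("all dataset counts must be >= 1")
    if fingers_per_subject > len(FINGER_LABELS):
        raise ValueError(
            f"at most {len(FINGER_LABELS)} fingers per subject ({FINGER_LABELS})"
        )
    root = Path(root)
    entries = []
    for s in range(n_subjects):
        subject = f"S{s + 1:03d}"
        for f in range(fingers_per_subject):
            finger = FINGER_LABELS[f]
            for k in range(1, samples_per_finger + 1):
                entries.append(
                    IndexEntry(
                        subject_id=subject,
                        finger=finger,
                        sample=k,
                        path=root / subject / f"{finger}_{k:02d}.{fmt}",
                    )
                )
    return DatasetIndex(entries)


def generate_dataset(
    n_subjects: int,
    fingers_per_subject: int,
    samples_per_finger: int,
    root_seed: int,
    out_dir: str | Path,
    params: CaptureParams = CaptureParams(),
    fmt: str = "png",
) -> DatasetIndex:
    """Write a full synthetic dataset plus its ``manifest.csv``.

    Finger models are derived from ``root_seed`` and the flat finger
    index; samples from the per-finger model and the sample number, so
    the whole dataset is reproducible from the call arguments alone.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = dataset_layout(
        n_subjects, fingers_per_subject, samples_per_finger, out_dir, fmt
    )
    finger_index = -1
    model = None
    last_finger = None
    for e in index.entries:
        if e.finger_id != last_finger:
            finger_index += 1
            model = make_finger_model(_finger_seed(root_seed, finger_index))
            last_finger = e.finger_id
        image = generate_finger_image(model, e.sample, params)
        e.path.parent.mkdir(parents=True, exist_ok=True)
        save_image(image, e.path)
    save_dataset_index(index, out_dir / "manifest.csv")
    return index
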