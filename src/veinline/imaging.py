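"""Grayscale image I/O and the subject/finger/sample dataset index.

Images are plain 2-D ``numpy.uint8`` arrays addressed row-major as
``(row, col)`` with intensities in ``[0, 255]``.  Supported on-disk formats
are binary PGM (P5, maxval 255) and grayscale PNG — both lossless and
sufficient for 8-bit near-infrared captures.

A dataset is described by a CSV manifest with header
``subject,finger,sample,path`` where ``finger`` is one of the four finger
labels used for enrollment and ``path`` is resolved relative to the
manifest's directory.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "FINGER_LABELS",
    "ImageFormatError",
    "ManifestError",
    "IndexEntry",
    "DatasetIndex",
    "as_gray_image",
    "load_image",
    "save_image",
    "load_dataset_index",
    "save_dataset_index",
]

FINGER_LABELS = ("left-index", "left-middle", "right-index", "right-middle")

_SUPPORTED_SUFFIXES = {".png", ".pgm"}


class ImageFormatError(ValueError):
    """The file exists but is not a readable raster image."""


class ManifestError(ValueError):
    """The dataset manifest is malformed or inconsistent."""


def as_gray_image(pixels: np.ndarray) -> np.ndarray:
    """Validate and coerce ``pixels`` into a uint8 grayscale image.

    Raises :class:`ValueError` for non-2D input or intensities outside
    ``[0, 255]``.
    """
    arr = np.asarray(pixels)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if np.any((arr < 0) | (arr > 255)):
            raise ValueError("intensities must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG or PGM file as a grayscale image.

    Color inputs are converted by ITU-R 601-2 luminance; an image whose
    three channels are equal therefore maps to that common gray value.

    Raises :class:`FileNotFoundError` if the file is missing and
    :class:`ImageFormatError` if it cannot be decoded as a raster.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with Image.open(path) as img:
            gray = img.convert("L")
            arr = np.asarray(gray, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise ImageFormatError(f"cannot decode raster image: {path}") from exc
    return as_gray_image(arr)


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write a grayscale image as PNG or binary PGM (by file suffix)."""
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ImageFormatError(
            f"unsupported image format {path.suffix!r}; use .png or .pgm"
        )
    arr = as_gray_image(image)
    Image.fromarray(arr, mode="L").save(path)


@dataclass(frozen=True)
class IndexEntry:
    """One image of one finger of one subject."""

    subject_id: str
    finger: str
    sample: int
    path: Path

    @property
    def finger_id(self) -> tuple[str, str]:
        """Identity of the physical finger: (subject, finger label)."""
        return (self.subject_id, self.finger)


@dataclass
class DatasetIndex:
    """Validated collection of dataset entries."""

    entries: list[IndexEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def finger_ids(self) -> list[tuple[str, str]]:
        """Distinct fingers, in first-seen order."""
        seen: dict[tuple[str, str], None] = {}
        for e in self.entries:
            seen.setdefault(e.finger_id, None)
        return list(seen)

    def counts_per_finger(self) -> dict[tuple[str, str], int]:
        counts: dict[tuple[str, str], int] = {}
        for e in self.entries:
            counts[e.finger_id] = counts.get(e.finger_id, 0) + 1
        return counts


def _validate_entries(entries: list[IndexEntry], check_paths: bool) -> None:
    seen: set[tuple[str, str, int]] = set()
    for e in entries:
        if e.finger not in FINGER_LABELS:
            raise ManifestError(
                f"unknown finger label {e.finger!r}; expected one of {FINGER_LABELS}"
            )
        triple = (e.subject_id, e.finger, e.sample)
        if triple in seen:
            raise ManifestError(f"duplicate (subject, finger, sample) triple: {triple}")
        seen.add(triple)
        if check_paths and not e.path.is_file():
            raise ManifestError(f"unresolvable image path: {e.path}")


def load_dataset_index(
    manifest: str | Path, *, check_paths: bool = True
) -> DatasetIndex:
    """Load and validate a CSV dataset manifest.

    Relative image paths are resolved against the manifest's directory.
    ``check_paths=False`` skips the existence check (useful when only the
    index structure is needed).
    """
    manifest = Path(manifest)
    if not manifest.is_file():
        raise FileNotFoundError(f"manifest not found: {manifest}")
    root = manifest.parent
    entries: list[IndexEntry] = []
    with open(manifest, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"subject", "finger", "sample", "path"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ManifestError(
                f"manifest must have columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            try:
                sample = int(row["sample"])
            except ValueError as exc:
                raise ManifestError(f"non-integer sample number: {row['sample']!r}") from exc
            path = Path(row["path"])
            if not path.is_absolute():
                path = root / path
            entries.append(
                IndexEntry(
                    subject_id=row["subject"],
                    finger=row["finger"],
                    sample=sample,
                    path=path,
                )
            )
    _validate_entries(entries, check_paths)
    return DatasetIndex(entries)


def save_dataset_index(index: DatasetIndex, manifest: str | Path) -> None:
    """Write a dataset index as a CSV manifest with relative paths."""
    manifest = Path(manifest)
    root = manifest.parent
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject", "finger", "sample", "path"])
        for e in index.entries:
            try:
                rel = e.path.relative_to(root)
            except ValueError:
                rel = e.path
            writer.writerow([e.subject_id, e.finger, e.sample, rel.as_posix()])
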