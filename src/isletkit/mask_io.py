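"""Raster and mask I/O, pixel-size tables and islet connected-component labeling.

Dithizone-stained islet micrographs come with class-coded grayscale masks
(islet vs exocrine tissue vs background) and a per-image physical pixel size
in µm/px.  This module reads and writes those inputs and individuates islet
objects as connected components, which every downstream analysis (morphometry,
selection, contour metrics) operates on.

Conventions used throughout the package: 0-based (row, col) coordinates with
the origin at the top-left corner, y increasing downward.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
from scipy import ndimage


class TissueClass(IntEnum):
    """Pixel classes of a segmentation mask."""

    BACKGROUND = 0
    EXOCRINE = 1
    ISLET = 2


#: Default gray-level encoding of mask classes.  The three classes are a
#: property of the masks; the specific gray levels are a package convention
#: (white islets on black background, mid-gray exocrine tissue).
DEFAULT_ENCODING: dict[int, TissueClass] = {
    255: TissueClass.ISLET,
    128: TissueClass.EXOCRINE,
    0: TissueClass.BACKGROUND,
}

#: Sanity bounds for physical pixel sizes (µm/px).  Typical stereomicroscope
#: setups for islet counting sit in the low single digits.
PIXEL_SIZE_BOUNDS = (0.1, 20.0)


class MaskEncodingError(ValueError):
    """A mask contains gray levels not covered by the declared encoding."""


@dataclass(frozen=True)
class LabelMask:
    """Class-coded segmentation mask.

    Parameters
    ----------
    classes
        2-D int8 array of :class:`TissueClass` codes.
    encoding
        The gray-level → class mapping the mask was read with (used to write
        it back out losslessly).
    """

    classes: np.ndarray
    encoding: Mapping[int, TissueClass]

    def __post_init__(self) -> None:
        if self.classes.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.classes.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape  # type: ignore[return-value]

    def islet_pixels(self) -> np.ndarray:
        """Boolean array, True where the pixel class is ISLET."""
        return self.classes == TissueClass.ISLET


@dataclass(frozen=True)
class LabeledComponents:
    """Islet objects individuated as connected components.

    ``labels`` is 0 outside islet tissue and carries contiguous component
    ids 1..n_components on islet pixels.
    """

    labels: np.ndarray
    n_components: int
    connectivity: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def component_mask(self, label: int) -> np.ndarray:
        if not 1 <= label <= self.n_components:
            raise KeyError(f"unknown component label {label}")
        return self.labels == label


def read_image(path: str | Path) -> np.ndarray:
    """Read an RGB micrograph as an (H, W, 3) uint8 array.

    Grayscale input is broadcast to three channels; an alpha channel is
    dropped.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"unsupported image shape {arr.shape} in {path}")
    return np.ascontiguousarray(arr, dtype=np.uint8)


def write_image(image: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def read_mask(
    path: str | Path, encoding: Mapping[int, TissueClass] | None = None
) -> LabelMask:
    """Read a single-channel class-coded mask.

    Every gray level present in the file must be covered by ``encoding``
    (default :data:`DEFAULT_ENCODING`); an unmapped level raises
    :class:`MaskEncodingError` naming the offending levels, since silently
    guessing a tissue class would corrupt all downstream morphometry.
    """
    if encoding is None:
        encoding = DEFAULT_ENCODING
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(
            f"mask {path} must be single-channel grayscale, got shape {arr.shape}"
        )
    return mask_from_gray(np.asarray(arr), encoding)


def mask_from_gray(
    gray: np.ndarray, encoding: Mapping[int, TissueClass] | None = None
) -> LabelMask:
    """Apply a gray-level encoding to an in-memory 2-D array."""
    if encoding is None:
        encoding = DEFAULT_ENCODING
    gray = np.asarray(gray)
    present = np.unique(gray)
    unmapped = [int(g) for g in present if int(g) not in encoding]
    if unmapped:
        raise MaskEncodingError(
            f"mask contains gray level(s) {unmapped} not covered by the "
            f"encoding {sorted(encoding)}"
        )
    classes = np.zeros(gray.shape, dtype=np.int8)
    for level, cls in encoding.items():
        classes[gray == level] = int(cls)
    return LabelMask(classes=classes, encoding=dict(encoding))


def mask_to_gray(mask: LabelMask) -> np.ndarray:
    """Invert the encoding back to a uint8 gray image (lossless round-trip)."""
    inverse: dict[int, int] = {}
    for level, cls in mask.encoding.items():
        if int(cls) in inverse:
            raise ValueError(
                f"encoding maps two gray levels to class {TissueClass(cls).name}; "
                "cannot write a unique gray image"
            )
        inverse[int(cls)] = level
    gray = np.zeros(mask.classes.shape, dtype=np.uint8)
    for code, level in inverse.items():
        gray[mask.classes == code] = level
    return gray


def write_mask(mask: LabelMask, path: str | Path) -> None:
    iio.imwrite(Path(path), mask_to_gray(mask))


def read_pixel_size_table(path: str | Path) -> dict[str, float]:
    """Read a CSV mapping image identifiers to pixel sizes in µm/px.

    Expected header: ``image,pixel_size_um_per_px``.  Non-positive,
    non-numeric or out-of-range sizes and duplicate image ids are rejected
    with the offending row number (1-based, counting the header as row 1).
    """
    path = Path(path)
    table: dict[str, float] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected a header row") from None
        if len(header) < 2:
            raise ValueError(f"{path}: header must have image and pixel-size columns")
        for rownum, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ValueError(f"{path} row {rownum}: missing pixel size")
            image_id = row[0].strip()
            try:
                size = float(row[1])
            except ValueError:
                raise ValueError(
                    f"{path} row {rownum}: non-numeric pixel size {row[1]!r}"
                ) from None
            if size <= 0:
                raise ValueError(f"{path} row {rownum}: non-positive pixel size {size}")
            lo, hi = PIXEL_SIZE_BOUNDS
            if not lo <= size <= hi:
                raise ValueError(
                    f"{path} row {rownum}: pixel size {size} outside sanity "
                    f"bounds [{lo}, {hi}] µm/px"
                )
            if image_id in table:
                raise ValueError(f"{path} row {rownum}: duplicate image id {image_id!r}")
            table[image_id] = size
    return table


def write_pixel_size_table(table: Mapping[str, float], path: str | Path) -> None:
    with open(Path(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "pixel_size_um_per_px"])
        for image_id, size in table.items():
            writer.writerow([image_id, repr(float(size))])


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def label_islets(mask: LabelMask, connectivity: int = 8) -> LabeledComponents:
    """Label maximal connected sets of ISLET pixels.

    Connectivity 8 (the default) merges diagonally touching islet pixels,
    which is the usual choice for blob-like biological objects; 4 keeps
    diagonal contacts separate.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    labels, n = ndimage.label(mask.islet_pixels(), structure=_STRUCTURES[connectivity])
    return LabeledComponents(
        labels=labels.astype(np.int32), n_components=int(n), connectivity=connectivity
    )
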