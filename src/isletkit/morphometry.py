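"""Islet morphometry: equivalent diameters, size categories and IE volumes.

Isolated islets are quantified in islet equivalents (IE, also written IEQ):
the volume of a sphere 150 µm in diameter.  An islet's 2-D pixel area A (in
µm²) is converted to the equivalent-circle diameter

    d = 2 * sqrt(A / pi)

and then, under the standard spherical model, to a volume

    V = (d / 150)**3  [IE]

i.e. the volume of a d-µm sphere divided by the volume of the 150 µm
reference sphere.  For manual-count emulation a stepwise mode is provided
instead, using the classical per-category IEQ conversion factors.

Islets are sorted into 50 µm diameter categories (50–100, 100–150, …),
labeled by the lower bin edge; bins are half-open, closed at the lower edge.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import ndimage

from .mask_io import LabeledComponents

#: Diameter of the reference sphere defining one islet equivalent, in µm.
IE_REFERENCE_DIAMETER_UM = 150.0

#: Classical stepwise IEQ conversion factors per 50 µm size category
#: (lower bin edge in µm → IE per islet), used by manual counting with an
#: eyepiece reticle.  Islets of 350 µm and above share the top factor.
RICORDI_FACTORS: dict[int, float] = {
    50: 0.167,
    100: 0.648,
    150: 1.685,
    200: 3.500,
    250: 6.315,
    300: 10.352,
    350: 15.833,
}


@dataclass(frozen=True)
class IsletRecord:
    """Geometry and morphometry of one labeled islet object."""

    islet_label: int
    area_px: int
    area_um2: float
    eq_diameter_um: float
    size_category: int
    volume_ie: float
    centroid: tuple[float, float]
    embedded: bool = False


def equivalent_diameter(area_px: float, pixel_size: float) -> float:
    """Equivalent-circle diameter in µm of an islet of ``area_px`` pixels."""
    if area_px < 0:
        raise ValueError(f"area must be non-negative, got {area_px}")
    if pixel_size <= 0:
        raise ValueError(f"pixel size must be positive, got {pixel_size}")
    if area_px == 0:
        return 0.0
    return 2.0 * math.sqrt(area_px * pixel_size**2 / math.pi)


def size_category(diameter_um: float, bin_width_um: float = 50.0) -> int:
    """Lower edge (µm) of the half-open size bin containing the diameter.

    The lower edge is included: a 50.0 µm islet falls in category 50.
    """
    if diameter_um < 0:
        raise ValueError(f"diameter must be non-negative, got {diameter_um}")
    return int(math.floor(diameter_um / bin_width_um) * bin_width_um)


def islet_volume_ie(diameter_um: float, model: str = "spherical") -> float:
    """Islet volume in IE for an equivalent diameter in µm.

    ``model="spherical"`` (default) applies the continuous spherical model
    V = (d/150)³.  ``model="stepwise"`` looks up the classical per-category
    factor instead (0 below 50 µm).
    """
    if diameter_um < 0:
        raise ValueError(f"diameter must be non-negative, got {diameter_um}")
    if model == "spherical":
        return (diameter_um / IE_REFERENCE_DIAMETER_UM) ** 3
    if model == "stepwise":
        cat = min(size_category(diameter_um), max(RICORDI_FACTORS))
        return RICORDI_FACTORS.get(cat, 0.0)
    raise ValueError(f"unknown volume model {model!r}")


def area_for_volume_ie(volume_ie: float, pixel_size: float = 1.0) -> float:
    """Pixel area of a disc whose spherical-model volume is ``volume_ie``.

    Inverse of the area → diameter → IE chain; useful for constructing
    synthetic islets of prescribed volume.
    """
    if volume_ie < 0:
        raise ValueError("volume must be non-negative")
    d_um = IE_REFERENCE_DIAMETER_UM * volume_ie ** (1.0 / 3.0)
    return math.pi * (d_um / 2.0) ** 2 / pixel_size**2


def summarize_image(
    components: LabeledComponents, pixel_size: float, model: str = "spherical"
) -> list[IsletRecord]:
    """One :class:`IsletRecord` per component, sorted by label.

    The centroid is the arithmetic mean of the component's pixel
    coordinates, in (row, col).
    """
    if pixel_size <= 0:
        raise ValueError(f"pixel size must be positive, got {pixel_size}")
    n = components.n_components
    if n == 0:
        return []
    labels = components.labels
    index = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=index)
    centroids = ndimage.center_of_mass(np.ones_like(labels), labels, index=index)
    records = []
    for label, area, centroid in zip(index.tolist(), areas.tolist(), centroids):
        d = equivalent_diameter(area, pixel_size)
        records.append(
            IsletRecord(
                islet_label=int(label),
                area_px=int(round(area)),
                area_um2=area * pixel_size**2,
                eq_diameter_um=d,
                size_category=size_category(d),
                volume_ie=islet_volume_ie(d, model=model),
                centroid=(float(centroid[0]), float(centroid[1])),
            )
        )
    return records


def write_morphometry_csv(
    records_by_image: dict[str, Iterable[IsletRecord]], path: str | Path
) -> None:
    """Flat per-islet morphometry export."""
    with open(Path(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "image",
                "islet_label",
                "area_px",
                "area_um2",
                "eq_diameter_um",
                "size_category",
                "volume_ie",
                "centroid_row",
                "centroid_col",
            ]
        )
        for image_id, records in records_by_image.items():
            for rec in records:
                writer.writerow(
                    [
                        image_id,
                        rec.islet_label,
                        rec.area_px,
                        f"{rec.area_um2:.3f}",
                        f"{rec.eq_diameter_um:.3f}",
                        rec.size_category,
                        f"{rec.volume_ie:.6f}",
                        f"{rec.centroid[0]:.2f}",
                        f"{rec.centroid[1]:.2f}",
                    ]
                )
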