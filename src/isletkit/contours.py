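"""Islet boundary extraction and review-image rendering.

The review workflow shows experts the islet contours drawn on top of the
original micrograph: the boundary pixels of each labeled islet are isolated
from the mask and recolored on the RGB image.  Selected islets are marked
with arrow glyphs, and individual islets can be cropped out with a margin
for per-islet report images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.morphology import disk

from .mask_io import LabeledComponents

Coord = tuple[int, int]


@dataclass(frozen=True)
class BoundarySet:
    """Per-component inner-boundary pixels.

    A pixel is a boundary pixel of its component iff it belongs to the
    component and at least one of its 4-neighbors (or the image edge) lies
    outside the component.  This yields a 1-px closed edge composed of
    object pixels.
    """

    per_label: Mapping[int, frozenset[Coord]]
    shape: tuple[int, int]

    def all_pixels(self) -> frozenset[Coord]:
        out: set[Coord] = set()
        for pixels in self.per_label.values():
            out |= pixels
        return frozenset(out)


@dataclass(frozen=True)
class ArrowMark:
    """An arrow pointing at one selected islet's centroid."""

    target: Coord
    islet_label: int
    per_set_id: int


def extract_boundaries(components: LabeledComponents) -> BoundarySet:
    """Isolate the inner 4-neighbor boundary of every labeled component."""
    lab = components.labels
    # Pad with -1 so pixels on the image edge always see an "outside" neighbor.
    padded = np.pad(lab, 1, constant_values=-1)
    interior = np.ones(lab.shape, dtype=bool)
    h, w = lab.shape
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neighbor = padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
        interior &= neighbor == lab
    boundary = (lab > 0) & ~interior
    per_label: dict[int, frozenset[Coord]] = {}
    rows, cols = np.nonzero(boundary)
    for r, c, l in zip(rows.tolist(), cols.tolist(), lab[rows, cols].tolist()):
        per_label.setdefault(l, set()).add((r, c))  # type: ignore[arg-type]
    return BoundarySet(
        per_label={l: frozenset(px) for l, px in per_label.items()},
        shape=(h, w),
    )


def render_overlay(
    image: np.ndarray,
    boundaries: BoundarySet,
    color: tuple[int, int, int] = (255, 255, 255),
    thickness_px: int = 1,
) -> np.ndarray:
    """Recolor boundary pixels on a copy of the image.

    ``thickness_px`` widens the 1-px boundary by binary dilation with a disc
    of radius ``(thickness_px - 1) // 2``; no other pixel is touched.
    """
    image = np.asarray(image)
    if image.shape[:2] != boundaries.shape:
        raise ValueError(
            f"image shape {image.shape[:2]} does not match boundary shape "
            f"{boundaries.shape}"
        )
    if thickness_px < 1:
        raise ValueError("thickness_px must be >= 1")
    mask = np.zeros(boundaries.shape, dtype=bool)
    for r, c in boundaries.all_pixels():
        mask[r, c] = True
    radius = (thickness_px - 1) // 2
    if radius > 0:
        mask = ndimage.binary_dilation(mask, structure=disk(radius))
    out = image.copy()
    out[mask] = color
    return out


def crop_islet(
    image: np.ndarray, components: LabeledComponents, label: int, margin_px: int = 0
) -> np.ndarray:
    """Crop the bounding box of one component, expanded by a margin.

    The crop is clipped to the image bounds, so a margin larger than the
    image simply returns the whole image.
    """
    region = components.component_mask(label)
    rows, cols = np.nonzero(region)
    r0 = max(int(rows.min()) - margin_px, 0)
    r1 = min(int(rows.max()) + margin_px + 1, image.shape[0])
    c0 = max(int(cols.min()) - margin_px, 0)
    c1 = min(int(cols.max()) + margin_px + 1, image.shape[1])
    return np.ascontiguousarray(image[r0:r1, c0:c1])


def crop_bounds(
    components: LabeledComponents, label: int, margin_px: int = 0
) -> tuple[int, int, int, int]:
    """(r0, r1, c0, c1) half-open bounds of :func:`crop_islet`."""
    region = components.component_mask(label)
    rows, cols = np.nonzero(region)
    h, w = components.shape
    return (
        max(int(rows.min()) - margin_px, 0),
        min(int(rows.max()) + margin_px + 1, h),
        max(int(cols.min()) - margin_px, 0),
        min(int(cols.max()) + margin_px + 1, w),
    )


@dataclass(frozen=True)
class ArrowStyle:
    """Cosmetic parameters of the arrow glyph.

    The shaft runs toward the target at ``angle_deg`` (measured clockwise
    from the +col axis, in image coordinates), stopping ``gap_px`` short of
    it so the arrow sits next to the islet rather than on it.
    """

    length_px: int = 40
    angle_deg: float = 45.0
    gap_px: int = 6
    head_px: int = 8
    color: tuple[int, int, int] = (255, 255, 255)


def render_arrows(
    image: np.ndarray, marks: Iterable[ArrowMark], style: ArrowStyle | None = None
) -> np.ndarray:
    """Draw deterministic arrow glyphs pointing at each mark's target."""
    style = style or ArrowStyle()
    image = np.asarray(image)
    h, w = image.shape[:2]
    out = image.copy()
    for mark in marks:
        tr, tc = mark.target
        if not (0 <= tr < h and 0 <= tc < w):
            raise ValueError(
                f"arrow target {mark.target} outside image bounds {h}x{w}"
            )
        theta = np.deg2rad(style.angle_deg)
        # Unit vector pointing from tail toward the target.
        ur, uc = np.sin(theta), np.cos(theta)
        tip = (tr - style.gap_px * ur, tc - style.gap_px * uc)
        tail = (tip[0] - style.length_px * ur, tip[1] - style.length_px * uc)
        _draw_segment(out, tail, tip, style.color)
        # Two head strokes swept back from the tip.
        for sweep in (np.deg2rad(25), -np.deg2rad(25)):
            hr = np.sin(theta + np.pi + sweep)
            hc = np.cos(theta + np.pi + sweep)
            head_end = (tip[0] + style.head_px * hr, tip[1] + style.head_px * hc)
            _draw_segment(out, tip, head_end, style.color)
    return out


def _draw_segment(
    image: np.ndarray,
    a: tuple[float, float],
    b: tuple[float, float],
    color: tuple[int, int, int],
) -> None:
    rr, cc = draw_line(
        int(round(a[0])), int(round(a[1])), int(round(b[0])), int(round(b[1]))
    )
    keep = (rr >= 0) & (rr < image.shape[0]) & (cc >= 0) & (cc < image.shape[1])
    image[rr[keep], cc[keep]] = color
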