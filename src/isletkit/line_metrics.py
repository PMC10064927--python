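"""Expert drawing accuracy and volume-agreement metrics.

An expert's tracing of a 1-px template line (an islet separation line or a
full islet contour) is scored as follows: both polylines are rasterized to
8-connected pixel chains, trimmed to the islet mass of the ground-truth
segmentation, and compared by the symmetric mean nearest-neighbour distance
in pixels.  A mean distance below 2 px counts as good drawing accuracy.

Closed contours are instead compared by the volumes they enclose: the
polygon is filled, the pixel area converted to an equivalent diameter and
then to islet equivalents (IE) under the spherical model, and agreement is
expressed as the relative error RE = |V_expert − V_template| / V_template.
Repeatability of replicate tracings of the same islet is the coefficient of
variation (sample sd / mean) of the replicate volumes; replicate sets
containing a zero volume are excluded as non-repeatable rather than given a
misleading CV.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon

from .mask_io import LabeledComponents
from .morphometry import equivalent_diameter, islet_volume_ie

Coord = tuple[int, int]

#: Drawing accuracy threshold: mean line distance (px) below which a tracing
#: is considered good.
GOOD_ACCURACY_PX = 2.0


class LineRole(str, Enum):
    TEMPLATE = "TEMPLATE"
    EXPERT = "EXPERT"
    GROUND_TRUTH = "GROUND_TRUTH"


@dataclass(frozen=True)
class Polyline:
    """Ordered (row, col) vertices of an open or closed drawn line."""

    points: tuple[tuple[float, float], ...]
    closed: bool = False
    author: str = ""
    role: LineRole = LineRole.EXPERT

    def __post_init__(self) -> None:
        minimum = 3 if self.closed else 2
        if len(self.points) < minimum:
            raise ValueError(
                f"{'closed' if self.closed else 'open'} polyline needs at least "
                f"{minimum} points, got {len(self.points)}"
            )
        for p in self.points:
            if not (math.isfinite(p[0]) and math.isfinite(p[1])):
                raise ValueError(f"non-finite polyline coordinate {p}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)


@dataclass(frozen=True)
class AccuracyResult:
    """Line-distance accuracy of one expert tracing against one template."""

    avg_distance_px: float
    template_length_px: int
    verdict: str  # "GOOD" | "POOR"
    empty_trim: bool = False

    @property
    def good(self) -> bool:
        return self.verdict == "GOOD"


@dataclass(frozen=True)
class VolumeComparison:
    v_expert: float
    v_template: float
    relative_error: float
    normalized_volume: float


@dataclass(frozen=True)
class ReplicateStats:
    """Mean and coefficient of variation of replicate contour volumes."""

    volumes: tuple[float, ...]
    mean: float
    cv: float | None
    excluded: bool = False


def rasterize_polyline(line: Polyline) -> frozenset[Coord]:
    """8-connected 1-px pixel chain along the polyline (Bresenham segments).

    Vertices are rounded to the nearest pixel; a closed polyline also
    connects its last vertex back to the first.
    """
    pts = [(int(round(r)), int(round(c))) for r, c in line.points]
    if line.closed:
        pts = pts + [pts[0]]
    pixels: set[Coord] = set()
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        pixels.update(zip(rr.tolist(), cc.tolist()))
    if not pixels:  # degenerate single-point line
        pixels.add(pts[0])
    return frozenset(pixels)


def trim_to_islet(
    line_pixels: Iterable[Coord], components: LabeledComponents, label: int
) -> frozenset[Coord]:
    """Keep only the pixels lying inside the given islet component.

    Separation lines are meaningful only within the islet mass; overhanging
    ends are discarded.  The result may be empty.
    """
    pixels = list(line_pixels)
    if not pixels:
        raise ValueError("cannot trim an empty pixel set")
    region = components.component_mask(label)
    h, w = region.shape
    return frozenset(
        (r, c) for r, c in pixels if 0 <= r < h and 0 <= c < w and region[r, c]
    )


def average_line_distance(
    a: Iterable[Coord], b: Iterable[Coord], symmetric: bool = True
) -> float:
    """Mean nearest-neighbour Euclidean distance between two pixel sets.

    The symmetric form (default) averages the directed means a→b and b→a,
    which is zero iff the sets are equal and has no direction bias; the
    directed form returns the a→b mean only.
    """
    arr_a = np.asarray(sorted(set(a)), dtype=float)
    arr_b = np.asarray(sorted(set(b)), dtype=float)
    if arr_a.size == 0 or arr_b.size == 0:
        raise ValueError("average_line_distance requires two nonempty pixel sets")
    d_ab = cKDTree(arr_b).query(arr_a)[0].mean()
    if not symmetric:
        return float(d_ab)
    d_ba = cKDTree(arr_a).query(arr_b)[0].mean()
    return float((d_ab + d_ba) / 2.0)


def score_accuracy(
    expert_line: Polyline,
    template_line: Polyline,
    components: LabeledComponents,
    label: int,
    symmetric: bool = True,
) -> AccuracyResult:
    """Rasterize, trim to the islet, measure, and apply the 2 px rule.

    If trimming empties either line (the tracing never entered the islet),
    the result is flagged and scored POOR with an infinite distance.
    """
    expert_px = trim_to_islet(rasterize_polyline(expert_line), components, label)
    template_px = trim_to_islet(rasterize_polyline(template_line), components, label)
    if not expert_px or not template_px:
        return AccuracyResult(
            avg_distance_px=math.inf,
            template_length_px=len(template_px),
            verdict="POOR",
            empty_trim=True,
        )
    d = average_line_distance(expert_px, template_px, symmetric=symmetric)
    verdict = "GOOD" if d < GOOD_ACCURACY_PX else "POOR"
    return AccuracyResult(
        avg_distance_px=d, template_length_px=len(template_px), verdict=verdict
    )


def enclosed_area_px(contour: Polyline) -> int:
    """Pixel count of the filled polygon (even-odd fill of the raster path).

    Matches the mask-based analysis path where contours are converted to
    binary masks before measurement; the shoelace area is the analytic
    cross-check used in tests.
    """
    if not contour.closed:
        raise ValueError("area is defined for closed contours only")
    arr = contour.as_array()
    rr, cc = draw_polygon(arr[:, 0], arr[:, 1])
    return int(rr.size)


def shoelace_area(contour: Polyline) -> float:
    """Analytic polygon area from vertex coordinates (cross-check oracle)."""
    arr = contour.as_array()
    r, c = arr[:, 0], arr[:, 1]
    return float(abs(np.dot(c, np.roll(r, -1)) - np.dot(r, np.roll(c, -1))) / 2.0)


def contour_volume(contour: Polyline, pixel_size: float) -> float:
    """IE volume enclosed by a closed contour at the given pixel size."""
    if shoelace_area(contour) == 0.0:
        warnings.warn("degenerate zero-area contour; volume set to 0 IE", stacklevel=2)
        return 0.0
    return islet_volume_ie(equivalent_diameter(enclosed_area_px(contour), pixel_size))


def compare_volumes(v_expert: float, v_template: float) -> VolumeComparison:
    """Relative error and normalized volume of an expert contour's IE volume."""
    if v_template <= 0:
        raise ValueError(f"template volume must be positive, got {v_template}")
    return VolumeComparison(
        v_expert=v_expert,
        v_template=v_template,
        relative_error=abs(v_expert - v_template) / v_template,
        normalized_volume=v_expert / v_template,
    )


def write_polylines_csv(
    records: Sequence[tuple[str, str, "Polyline"]], path
) -> None:
    """Write (image, line_id, polyline) records to the CSV interchange format.

    Columns: image, line_id, author, role, closed, point_index, row, col —
    one row per vertex, vertices ordered by point_index within a line.
    """
    import csv
    from pathlib import Path

    with open(Path(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["image", "line_id", "author", "role", "closed", "point_index", "row", "col"]
        )
        for image, line_id, line in records:
            for idx, (r, c) in enumerate(line.points):
                writer.writerow(
                    [
                        image,
                        line_id,
                        line.author,
                        line.role.value,
                        int(line.closed),
                        idx,
                        repr(float(r)),
                        repr(float(c)),
                    ]
                )


def read_polylines_csv(path) -> list[tuple[str, str, "Polyline"]]:
    """Inverse of :func:`write_polylines_csv` (vertex order restored).

    Several lines may share the same (image, line_id, author, role) key —
    replicate tracings of one template do.  A ``point_index`` reset (a value
    not larger than its predecessor) starts a new polyline within the key.
    """
    import csv
    from pathlib import Path

    groups: dict[tuple[str, str, str, str, int], list[list[tuple[int, float, float]]]] = {}
    order: list[tuple] = []
    with open(Path(path), newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            key = (
                row["image"],
                row["line_id"],
                row["author"],
                row["role"],
                int(row["closed"]),
            )
            if key not in groups:
                groups[key] = []
                order.append(key)
            idx = int(row["point_index"])
            runs = groups[key]
            if not runs or (runs[-1] and idx <= runs[-1][-1][0]):
                runs.append([])
            runs[-1].append((idx, float(row["row"]), float(row["col"])))
    out = []
    for key in order:
        image, line_id, author, role, closed = key
        for run in groups[key]:
            pts = tuple((r, c) for _, r, c in run)
            out.append(
                (
                    image,
                    line_id,
                    Polyline(points=pts, closed=bool(closed), author=author, role=LineRole(role)),
                )
            )
    return out


def polyline_to_json(line: Polyline) -> dict:
    """JSON list-of-points dialect of a polyline."""
    return {
        "points": [[float(r), float(c)] for r, c in line.points],
        "closed": line.closed,
        "author": line.author,
        "role": line.role.value,
    }


def polyline_from_json(obj: dict) -> Polyline:
    return Polyline(
        points=tuple((float(r), float(c)) for r, c in obj["points"]),
        closed=bool(obj["closed"]),
        author=obj.get("author", ""),
        role=LineRole(obj.get("role", "EXPERT")),
    )


def replicate_cv(volumes: Sequence[float], ddof: int = 1) -> ReplicateStats:
    """Coefficient of variation of replicate volumes (repeatability).

    Uses the sample (n−1) standard deviation by default.  A replicate set
    containing a zero volume is excluded (cv=None): a zero replicate means
    the object was not recognised at all, and a CV over such a set would
    measure recognition failure, not drawing repeatability.
    """
    vols = tuple(float(v) for v in volumes)
    if len(vols) < 2:
        raise ValueError("replicate CV requires at least 2 volumes")
    if any(v < 0 for v in vols):
        raise ValueError("volumes must be non-negative")
    mean = float(np.mean(vols))
    if any(v == 0.0 for v in vols):
        return ReplicateStats(volumes=vols, mean=mean, cv=None, excluded=True)
    sd = float(np.std(vols, ddof=ddof))
    return ReplicateStats(volumes=vols, mean=mean, cv=sd / mean, excluded=False)
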