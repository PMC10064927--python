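"""Expert opinions: validation, tallies, CSV interchange and consensus reports.

Experts submit three kinds of opinion on a review set: a qualitative
micrograph-quality class per image (good / borderline / unacceptable), a
True/False/skip verdict per marked islet contour, and — when a contour is
disputed — graphical edits: partial disagreement strokes, separation lines
between adjacent islets, include/exclude regions, full redraws, a missing
contour, or a flat "this is not an islet".  A consensus report renders, for
every disputed islet, a cropped image with the ground-truth boundary in one
color and all (anonymized) expert edits in another, plus a CSV tally.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from . import contours
from .line_metrics import Polyline, rasterize_polyline
from .mask_io import label_islets, write_image
from .selection import Bundle, SelectionManifest


class Quality(str, Enum):
    GOOD = "GOOD"
    BORDERLINE = "BORDERLINE"
    UNACCEPTABLE = "UNACCEPTABLE"


class Verdict(str, Enum):
    TRUE_CONTOUR = "TRUE_CONTOUR"
    FALSE_CONTOUR = "FALSE_CONTOUR"
    SKIPPED = "SKIPPED"


class EditKind(str, Enum):
    PARTIAL_DISAGREEMENT = "PARTIAL_DISAGREEMENT"
    NOT_AN_ISLET = "NOT_AN_ISLET"
    SEPARATION_LINE = "SEPARATION_LINE"
    INCLUDE_PART = "INCLUDE_PART"
    EXCLUDE_PART = "EXCLUDE_PART"
    FULL_REDRAW = "FULL_REDRAW"
    MISSING_CONTOUR = "MISSING_CONTOUR"


#: Edit kinds whose geometry must be a closed contour / an open line.
_CLOSED_KINDS = {EditKind.FULL_REDRAW, EditKind.MISSING_CONTOUR}
_OPEN_KINDS = {EditKind.SEPARATION_LINE}


@dataclass(frozen=True)
class GraphicalEdit:
    kind: EditKind
    geometry: Polyline | None = None


@dataclass(frozen=True)
class ImageOpinion:
    expert: str
    image: str
    quality: Quality
    note: str = ""


@dataclass(frozen=True)
class IsletOpinion:
    expert: str
    image: str
    islet: int  # per-set islet number
    verdict: Verdict
    edits: tuple[GraphicalEdit, ...] = field(default_factory=tuple)
    note: str = ""

    @property
    def is_graphical(self) -> bool:
        """True if the opinion carries at least one graphical edit."""
        return len(self.edits) > 0


class OpinionValidationError(ValueError):
    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


def validate_opinion(
    op: ImageOpinion | IsletOpinion, manifest: SelectionManifest
) -> list[str]:
    """Return the list of rule violations for one opinion (empty = valid)."""
    violations: list[str] = []
    images = {e.image_id: e for e in manifest.entries}
    if op.image not in images:
        violations.append(f"unknown image {op.image!r}")
        return violations
    if isinstance(op, ImageOpinion):
        return violations
    islet_nos = {p.set_islet_no for p in images[op.image].islets}
    if op.islet not in islet_nos:
        violations.append(f"unknown islet {op.islet} in image {op.image!r}")
    if op.verdict is not Verdict.FALSE_CONTOUR and op.edits:
        violations.append(f"{op.verdict.value} opinion must not carry edits")
    for edit in op.edits:
        geom = edit.geometry
        if edit.kind is EditKind.NOT_AN_ISLET:
            if geom is not None:
                violations.append("NOT_AN_ISLET carries no geometry")
        elif geom is None:
            violations.append(f"{edit.kind.value} requires geometry")
        elif edit.kind in _CLOSED_KINDS and not geom.closed:
            violations.append(f"{edit.kind.value} geometry must be closed")
        elif edit.kind in _OPEN_KINDS and geom.closed:
            violations.append(f"{edit.kind.value} geometry must be open")
    return violations


def validate_opinions(
    ops: list[ImageOpinion | IsletOpinion], manifest: SelectionManifest
) -> None:
    """Validate a whole submission; duplicates per (expert, target) are rejected."""
    violations: list[str] = []
    seen: set[tuple] = set()
    for op in ops:
        key = (
            (op.expert, op.image)
            if isinstance(op, ImageOpinion)
            else (op.expert, op.image, op.islet)
        )
        if key in seen:
            violations.append(f"duplicate opinion for {key}")
        seen.add(key)
        violations.extend(validate_opinion(op, manifest))
    if violations:
        raise OpinionValidationError(violations)


@dataclass(frozen=True)
class ImageTally:
    image: str
    counts: dict[str, int]
    unanimous: bool


def tally_image_classifications(ops: list[ImageOpinion]) -> dict[str, ImageTally]:
    """Per-image counts of each quality class with a unanimity flag."""
    by_image: dict[str, list[ImageOpinion]] = {}
    for op in ops:
        by_image.setdefault(op.image, []).append(op)
    out = {}
    for image, group in sorted(by_image.items()):
        counts = {q.value: 0 for q in Quality}
        for op in group:
            counts[op.quality.value] += 1
        nonzero = [q for q, n in counts.items() if n > 0]
        out[image] = ImageTally(image=image, counts=counts, unanimous=len(nonzero) == 1)
    return out


@dataclass(frozen=True)
class IsletTally:
    image: str
    islet: int
    verdict_counts: dict[str, int]
    edit_kind_counts: dict[str, int]
    experts_with_edits: tuple[str, ...]

    @property
    def disputed(self) -> bool:
        return len(self.experts_with_edits) > 0


@dataclass(frozen=True)
class OpinionTotals:
    n_graphical_opinions: int
    n_disputed_islets: int
    per_islet: dict[tuple[str, int], IsletTally]


def tally_islet_opinions(ops: list[IsletOpinion]) -> OpinionTotals:
    """Per-islet verdict/edit tallies and set-level totals.

    A *graphical opinion* is an islet opinion carrying at least one edit; a
    *disputed* islet received at least one graphical opinion.
    """
    by_islet: dict[tuple[str, int], list[IsletOpinion]] = {}
    for op in ops:
        by_islet.setdefault((op.image, op.islet), []).append(op)
    per_islet = {}
    for key, group in sorted(by_islet.items()):
        verdicts = {v.value: 0 for v in Verdict}
        kinds = {k.value: 0 for k in EditKind}
        editors = []
        for op in group:
            verdicts[op.verdict.value] += 1
            for edit in op.edits:
                kinds[edit.kind.value] += 1
            if op.is_graphical:
                editors.append(op.expert)
        per_islet[key] = IsletTally(
            image=key[0],
            islet=key[1],
            verdict_counts=verdicts,
            edit_kind_counts=kinds,
            experts_with_edits=tuple(sorted(set(editors))),
        )
    return OpinionTotals(
        n_graphical_opinions=sum(1 for op in ops if op.is_graphical),
        n_disputed_islets=sum(1 for t in per_islet.values() if t.disputed),
        per_islet=per_islet,
    )


# -- CSV interchange ---------------------------------------------------------

OPINION_COLUMNS = [
    "expert",
    "image",
    "islet",
    "kind",
    "value",
    "edits_json",
    "note",
]


def _polyline_to_json(line: Polyline | None):
    if line is None:
        return None
    return {"points": [list(p) for p in line.points], "closed": line.closed}


def _polyline_from_json(obj, author: str) -> Polyline | None:
    if obj is None:
        return None
    return Polyline(
        points=tuple((float(r), float(c)) for r, c in obj["points"]),
        closed=bool(obj["closed"]),
        author=author,
    )


def write_opinions_csv(
    ops: list[ImageOpinion | IsletOpinion], path: str | Path
) -> None:
    """One row per opinion; graphical edits serialized as JSON in a column."""
    with open(Path(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(OPINION_COLUMNS)
        for op in ops:
            if isinstance(op, ImageOpinion):
                writer.writerow(
                    [op.expert, op.image, "", "IMAGE", op.quality.value, "", op.note]
                )
            else:
                edits = json.dumps(
                    [
                        {"kind": e.kind.value, "geometry": _polyline_to_json(e.geometry)}
                        for e in op.edits
                    ]
                ) if op.edits else ""
                writer.writerow(
                    [op.expert, op.image, op.islet, "ISLET", op.verdict.value, edits, op.note]
                )


def read_opinions_csv(path: str | Path) -> list[ImageOpinion | IsletOpinion]:
    ops: list[ImageOpinion | IsletOpinion] = []
    with open(Path(path), newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            if row["kind"] == "IMAGE":
                ops.append(
                    ImageOpinion(
                        expert=row["expert"],
                        image=row["image"],
                        quality=Quality(row["value"]),
                        note=row["note"],
                    )
                )
            else:
                edits = tuple(
                    GraphicalEdit(
                        kind=EditKind(e["kind"]),
                        geometry=_polyline_from_json(e["geometry"], row["expert"]),
                    )
                    for e in json.loads(row["edits_json"])
                ) if row["edits_json"] else ()
                ops.append(
                    IsletOpinion(
                        expert=row["expert"],
                        image=row["image"],
                        islet=int(row["islet"]),
                        verdict=Verdict(row["value"]),
                        edits=edits,
                        note=row["note"],
                    )
                )
    return ops


# -- Consensus report --------------------------------------------------------

GROUND_TRUTH_COLOR = (60, 90, 255)  # blue
EXPERT_COLOR = (255, 255, 255)  # white


def consensus_report(
    manifest: SelectionManifest,
    ops: list[ImageOpinion | IsletOpinion],
    bundle: Bundle,
    out_dir: str | Path,
    margin_px: int = 20,
    gt_color: tuple[int, int, int] = GROUND_TRUTH_COLOR,
    expert_color: tuple[int, int, int] = EXPERT_COLOR,
) -> Path:
    """Write per-disputed-islet crops and a consensus.csv summary.

    Every crop shows the ground-truth boundary in ``gt_color`` with all
    expert edits overlaid in ``expert_color``.  Expert identities are
    anonymized to stable labels e1..eN (order of first appearance in the
    submitted opinions).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    islet_ops = [op for op in ops if isinstance(op, IsletOpinion)]
    validate_opinions(list(ops), manifest)
    totals = tally_islet_opinions(islet_ops)

    anon: dict[str, str] = {}
    for op in islet_ops:
        if op.expert not in anon:
            anon[op.expert] = f"e{len(anon) + 1}"

    pick_by_no = {
        (e.image_id, p.set_islet_no): p for e in manifest.entries for p in e.islets
    }
    rows = []
    for (image, islet_no), tally in totals.per_islet.items():
        crop_name = ""
        if tally.disputed:
            crop_name = f"{image}_islet{islet_no}.png"
            _render_consensus_crop(
                bundle,
                image,
                pick_by_no[(image, islet_no)].islet_label,
                [op for op in islet_ops if op.image == image and op.islet == islet_no],
                out_dir / crop_name,
                margin_px,
                gt_color,
                expert_color,
            )
        rows.append(
            {
                "image": image,
                "set_islet_no": islet_no,
                "n_true": tally.verdict_counts["TRUE_CONTOUR"],
                "n_false": tally.verdict_counts["FALSE_CONTOUR"],
                "n_skipped": tally.verdict_counts["SKIPPED"],
                "n_graphical": len(tally.experts_with_edits),
                "editors": ",".join(anon[e] for e in tally.experts_with_edits),
                "edit_kinds": ";".join(
                    f"{k}={n}" for k, n in tally.edit_kind_counts.items() if n > 0
                ),
                "crop": crop_name,
            }
        )
    csv_path = out_dir / "consensus.csv"
    with open(csv_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]) if rows else ["image"])
        writer.writeheader()
        writer.writerows(rows)
    return csv_path


def _render_consensus_crop(
    bundle: Bundle,
    image_id: str,
    islet_label: int,
    islet_ops: list[IsletOpinion],
    path: Path,
    margin_px: int,
    gt_color: tuple[int, int, int],
    expert_color: tuple[int, int, int],
) -> None:
    comps = label_islets(bundle.masks[image_id])
    r0, r1, c0, c1 = contours.crop_bounds(comps, islet_label, margin_px)
    img = bundle.images[image_id].copy()
    # Ground-truth boundary of this islet only.
    bset = contours.extract_boundaries(comps)
    for r, c in bset.per_label.get(islet_label, frozenset()):
        img[r, c] = gt_color
    h, w = img.shape[:2]
    for op in islet_ops:
        for edit in op.edits:
            if edit.geometry is None:
                continue
            for r, c in rasterize_polyline(edit.geometry):
                if 0 <= r < h and 0 <= c < w:
                    img[r, c] = expert_color
    write_image(img[r0:r1, c0:c1], path)
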