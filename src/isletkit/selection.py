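"""Review-set assembly: random image and stratified islet selection.

Two workflows are supported.  In the *validation* workflow an engine draws a
preset number of random images from a bundle and, within each image, random
islets stratified over the 50 µm size categories above an adjustable size
threshold, so that every occupied category is represented.  In the *inquiry*
workflow a reviewer hand-picks islets on a single image.  Either way the
result is a :class:`SelectionManifest` giving every chosen image and islet a
per-set identification number, reproducible from the recorded seed.
"""

from __future__ import annotations

import csv
import tempfile
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import contours
from .mask_io import (
    LabelMask,
    TissueClass,
    label_islets,
    read_image,
    read_mask,
    read_pixel_size_table,
    write_image,
)
from .morphometry import IsletRecord, summarize_image


@dataclass(frozen=True)
class IsletPick:
    islet_label: int
    set_islet_no: int
    centroid: tuple[float, float]
    size_category: int


@dataclass(frozen=True)
class ManifestEntry:
    image_id: str
    set_image_no: int
    islets: tuple[IsletPick, ...]


@dataclass(frozen=True)
class SelectionManifest:
    """A reviewable set: images and marked islets with per-set numbering."""

    set_name: str
    seed: int
    size_threshold_um: float
    mode: str  # "VALIDATION" | "INQUIRY"
    entries: tuple[ManifestEntry, ...] = field(default_factory=tuple)

    def n_islets(self) -> int:
        return sum(len(e.islets) for e in self.entries)

    def image_ids(self) -> list[str]:
        return [e.image_id for e in self.entries]


@dataclass
class Bundle:
    """In-memory image/mask/pixel-size bundle keyed by image id (file stem)."""

    images: dict[str, np.ndarray]
    masks: dict[str, LabelMask]
    pixel_sizes: dict[str, float]

    def component_map(self, connectivity: int = 8):
        return {iid: label_islets(m, connectivity) for iid, m in self.masks.items()}


def load_bundle(path: str | Path, encoding=None) -> Bundle:
    """Load a bundle directory (or zip) with images/, masks/, pixel_sizes.csv.

    Masks are matched to images by file stem; every image must have a mask
    and a pixel size.  Duplicate stems within a directory are an error.
    """
    path = Path(path)
    if path.suffix == ".zip":
        tmp = tempfile.mkdtemp(prefix="isletkit_bundle_")
        with zipfile.ZipFile(path) as zf:
            zf.extractall(tmp)
        path = Path(tmp)
        # A zip may wrap everything in a single top-level folder.
        if not (path / "images").is_dir():
            subdirs = [p for p in path.iterdir() if p.is_dir()]
            if len(subdirs) == 1 and (subdirs[0] / "images").is_dir():
                path = subdirs[0]
    images_dir, masks_dir = path / "images", path / "masks"
    csv_path = path / "pixel_sizes.csv"
    for required in (images_dir, masks_dir):
        if not required.is_dir():
            raise FileNotFoundError(f"bundle is missing {required}")
    if not csv_path.is_file():
        raise FileNotFoundError(f"bundle is missing {csv_path}")

    def collect(directory: Path) -> dict[str, Path]:
        out: dict[str, Path] = {}
        for p in sorted(directory.iterdir()):
            if p.suffix.lower() not in {".png", ".tif", ".tiff"}:
                continue
            if p.stem in out:
                raise ValueError(f"duplicate image id {p.stem!r} in {directory}")
            out[p.stem] = p
        return out

    image_paths = collect(images_dir)
    mask_paths = collect(masks_dir)
    pixel_sizes = read_pixel_size_table(csv_path)
    for iid in image_paths:
        if iid not in mask_paths:
            raise ValueError(f"image {iid!r} has no mask")
        if iid not in pixel_sizes:
            raise ValueError(f"image {iid!r} has no pixel size entry")
    return Bundle(
        images={iid: read_image(p) for iid, p in image_paths.items()},
        masks={iid: read_mask(p, encoding) for iid, p in mask_paths.items()},
        pixel_sizes={iid: pixel_sizes[iid] for iid in image_paths},
    )


def select_images(
    image_ids: list[str], n_images: int, rng: np.random.Generator
) -> list[str]:
    """Uniform sample of min(n_images, available) images without replacement.

    The sample keeps the original list order so per-set numbering is stable.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if not image_ids:
        raise ValueError("no candidate images")
    if n_images >= len(image_ids):
        return list(image_ids)
    idx = rng.choice(len(image_ids), size=n_images, replace=False)
    return [image_ids[i] for i in sorted(idx.tolist())]


def select_islets_stratified(
    records: list[IsletRecord],
    threshold_um: float,
    quota: int,
    rng: np.random.Generator,
) -> list[int]:
    """Stratified random islet draw over the 50 µm size categories.

    Only islets with equivalent diameter ≥ ``threshold_um`` are eligible.
    Categories are visited round-robin in ascending order, drawing uniformly
    without replacement within each, until ``quota`` islets are chosen or
    eligibility is exhausted — so whenever quota ≥ number of occupied
    categories, every occupied category is represented.
    """
    if quota < 1:
        raise ValueError("quota must be >= 1")
    eligible = [r for r in records if r.eq_diameter_um >= threshold_um]
    by_cat: dict[int, list[int]] = {}
    for r in eligible:
        by_cat.setdefault(r.size_category, []).append(r.islet_label)
    # Shuffle within each category (ascending order for determinism).
    queues = []
    for cat in sorted(by_cat):
        labels = by_cat[cat]
        order = rng.permutation(len(labels))
        queues.append([labels[i] for i in order.tolist()])
    chosen: list[int] = []
    while len(chosen) < quota and any(queues):
        for q in queues:
            if q and len(chosen) < quota:
                chosen.append(q.pop(0))
        queues = [q for q in queues if q]
    return chosen


def build_validation_set(
    bundle: Bundle,
    n_images: int,
    threshold_um: float = 50.0,
    quota_per_image: int = 7,
    seed: int = 0,
    set_name: str = "validation",
    out_dir: str | Path | None = None,
    connectivity: int = 8,
) -> SelectionManifest:
    """Run the automated engine: random images, stratified islets, numbering.

    A single generator seeded with ``seed`` drives first the image draw and
    then the per-image islet draws in per-set order, so the manifest is
    bit-reproducible.  If ``out_dir`` is given, arrow-marked review images
    and ``manifest.csv`` are written there.
    """
    ids = sorted(bundle.images)
    rng = np.random.default_rng(seed)
    chosen_images = select_images(ids, n_images, rng)
    entries = []
    for img_no, iid in enumerate(chosen_images, start=1):
        comps = label_islets(bundle.masks[iid], connectivity)
        records = summarize_image(comps, bundle.pixel_sizes[iid])
        rec_by_label = {r.islet_label: r for r in records}
        labels = select_islets_stratified(records, threshold_um, quota_per_image, rng)
        picks = tuple(
            IsletPick(
                islet_label=l,
                set_islet_no=k,
                centroid=rec_by_label[l].centroid,
                size_category=rec_by_label[l].size_category,
            )
            for k, l in enumerate(labels, start=1)
        )
        entries.append(ManifestEntry(image_id=iid, set_image_no=img_no, islets=picks))
    manifest = SelectionManifest(
        set_name=set_name,
        seed=seed,
        size_threshold_um=threshold_um,
        mode="VALIDATION",
        entries=tuple(entries),
    )
    if out_dir is not None:
        write_review_images(manifest, bundle, out_dir)
        write_manifest_csv(manifest, Path(out_dir) / "manifest.csv")
    return manifest


def build_inquiry_set(
    image_id: str,
    islet_labels: list[int],
    bundle: Bundle,
    set_name: str = "inquiry",
    connectivity: int = 8,
) -> SelectionManifest:
    """Manifest from hand-picked islet labels on a single image."""
    if not islet_labels:
        raise ValueError("inquiry requires at least one islet label")
    if len(set(islet_labels)) != len(islet_labels):
        raise ValueError("duplicate islet labels in inquiry list")
    if image_id not in bundle.masks:
        raise KeyError(f"unknown image {image_id!r}")
    comps = label_islets(bundle.masks[image_id], connectivity)
    records = {r.islet_label: r for r in summarize_image(comps, bundle.pixel_sizes[image_id])}
    picks = []
    for k, label in enumerate(islet_labels, start=1):
        if label not in records:
            raise KeyError(f"unknown islet label {label} in image {image_id!r}")
        rec = records[label]
        picks.append(
            IsletPick(
                islet_label=label,
                set_islet_no=k,
                centroid=rec.centroid,
                size_category=rec.size_category,
            )
        )
    return SelectionManifest(
        set_name=set_name,
        seed=0,
        size_threshold_um=0.0,
        mode="INQUIRY",
        entries=(ManifestEntry(image_id=image_id, set_image_no=1, islets=tuple(picks)),),
    )


def write_review_images(
    manifest: SelectionManifest, bundle: Bundle, out_dir: str | Path
) -> list[Path]:
    """Arrow-marked PNG per selected image (contour overlay + arrows)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for entry in manifest.entries:
        comps = label_islets(bundle.masks[entry.image_id])
        boundaries = contours.extract_boundaries(comps)
        img = contours.render_overlay(bundle.images[entry.image_id], boundaries)
        marks = [
            contours.ArrowMark(
                target=(int(round(p.centroid[0])), int(round(p.centroid[1]))),
                islet_label=p.islet_label,
                per_set_id=p.set_islet_no,
            )
            for p in entry.islets
        ]
        img = contours.render_arrows(img, marks)
        path = out_dir / f"{entry.image_id}_marked.png"
        write_image(img, path)
        written.append(path)
    return written


MANIFEST_COLUMNS = [
    "set_name",
    "seed",
    "mode",
    "size_threshold_um",
    "image",
    "set_image_no",
    "islet_label",
    "set_islet_no",
    "centroid_row",
    "centroid_col",
    "size_category",
]


def write_manifest_csv(manifest: SelectionManifest, path: str | Path) -> None:
    with open(Path(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for entry in manifest.entries:
            for pick in entry.islets:
                writer.writerow(
                    [
                        manifest.set_name,
                        manifest.seed,
                        manifest.mode,
                        f"{manifest.size_threshold_um:g}",
                        entry.image_id,
                        entry.set_image_no,
                        pick.islet_label,
                        pick.set_islet_no,
                        repr(pick.centroid[0]),
                        repr(pick.centroid[1]),
                        pick.size_category,
                    ]
                )


def read_manifest_csv(path: str | Path) -> SelectionManifest:
    with open(Path(path), newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise ValueError(f"{path}: empty manifest")
    first = rows[0]
    entries: dict[str, list[IsletPick]] = {}
    image_nos: dict[str, int] = {}
    for row in rows:
        iid = row["image"]
        image_nos[iid] = int(row["set_image_no"])
        entries.setdefault(iid, []).append(
            IsletPick(
                islet_label=int(row["islet_label"]),
                set_islet_no=int(row["set_islet_no"]),
                centroid=(float(row["centroid_row"]), float(row["centroid_col"])),
                size_category=int(row["size_category"]),
            )
        )
    ordered = sorted(entries, key=lambda iid: image_nos[iid])
    return SelectionManifest(
        set_name=first["set_name"],
        seed=int(first["seed"]),
        size_threshold_um=float(first["size_threshold_um"]),
        mode=first["mode"],
        entries=tuple(
            ManifestEntry(
                image_id=iid,
                set_image_no=image_nos[iid],
                islets=tuple(sorted(entries[iid], key=lambda p: p.set_islet_no)),
            )
            for iid in ordered
        ),
    )
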