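"""Synthetic islet scenes, template lines, simulated experts and opinions.

Real inputs are dithizone-stained micrographs with expert-drawn class masks.
This generator emulates them with known ground truth: blob-like islet
objects of controlled equivalent diameter (the study range is 50–400 µm) on
a light background with exocrine distractors, an exactly class-coded mask,
template polylines (separation chords and closed contours), and simulated
expert tracings with controlled perpendicular Gaussian jitter.  Everything
is deterministic given a seed; one master seed fans out to per-stage
generators by fixed offsets.

What it does not emulate: real staining variability, focus gradients,
debris, or the correlated (non-white) hand tremor of real drawing — so
passing tests demonstrate correctness of the measurement chain, not
robustness to real-world image artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .line_metrics import LineRole, Polyline, contour_volume
from .mask_io import (
    DEFAULT_ENCODING,
    LabelMask,
    LabeledComponents,
    TissueClass,
    label_islets,
    write_image,
    write_mask,
    write_pixel_size_table,
)
from .morphometry import summarize_image
from .opinions import (
    EditKind,
    GraphicalEdit,
    ImageOpinion,
    IsletOpinion,
    Quality,
    Verdict,
)
from .selection import Bundle, SelectionManifest

# Colors for the cosmetic RGB rendering (dithizone stains islets red).
_BACKGROUND_RGB = (236, 229, 216)
_ISLET_RGB = (186, 52, 66)
_EXOCRINE_RGB = (214, 188, 158)


@dataclass(frozen=True)
class IsletSpec:
    """One synthetic islet: position, physical size, shape and embedding."""

    center: tuple[int, int]
    eq_diameter_um: float
    shape: str = "disc"  # "disc" | "blob"
    irregularity: float = 0.15
    embedded: bool = False

    def __post_init__(self) -> None:
        if not 20.0 <= self.eq_diameter_um <= 500.0:
            raise ValueError(
                f"islet diameter {self.eq_diameter_um} µm outside the supported "
                "20–500 µm range"
            )
        if self.shape not in ("disc", "blob"):
            raise ValueError(f"unknown shape {self.shape!r}")


@dataclass(frozen=True)
class SceneSpec:
    shape_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 2.0
    islets: tuple[IsletSpec, ...] = field(default_factory=tuple)
    n_exocrine_distractors: int = 3
    seed: int = 0


@dataclass(frozen=True)
class ExpertProfile:
    """Behavioural parameters of one simulated expert.

    ``jitter_sigma_px`` is the sd of the perpendicular Gaussian displacement
    applied to traced vertices; ``p_false_call`` is the probability of
    disputing a contour (submitting a graphical redraw).
    """

    expert_id: str
    jitter_sigma_px: float = 1.0
    p_false_call: float = 0.2
    seed_offset: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_false_call <= 1.0:
            raise ValueError("p_false_call must be in [0, 1]")
        if self.jitter_sigma_px < 0:
            raise ValueError("jitter_sigma_px must be >= 0")


@dataclass(frozen=True)
class TrueIslet:
    """Generating parameters of one rendered islet (the ground truth)."""

    center: tuple[int, int]
    eq_diameter_um: float
    area_px: int
    embedded: bool


def _blob_radii(r0_px: float, irregularity: float, rng: np.random.Generator,
                n_vertices: int = 180) -> np.ndarray:
    """Radial profile of a blob: disc perturbed by low-order harmonics.

    The profile is rescaled so the enclosed (shoelace) area equals the
    disc's π·r0², keeping the equivalent diameter controllable.
    """
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    profile = np.ones(n_vertices)
    for k in (2, 3, 4):
        amp = irregularity * rng.uniform(0.3, 1.0) / k
        phase = rng.uniform(0.0, 2.0 * math.pi)
        profile += amp * np.cos(k * theta + phase)
    profile = np.maximum(profile, 0.2)
    r = r0_px * profile
    # Shoelace area of the polar polygon, then rescale to the disc area.
    rows, cols = r * np.sin(theta), r * np.cos(theta)
    area = 0.5 * abs(
        np.dot(cols, np.roll(rows, -1)) - np.dot(rows, np.roll(cols, -1))
    )
    r *= math.sqrt(math.pi * r0_px**2 / area)
    return r


def _islet_pixels(
    spec: IsletSpec, pixel_size_um: float, shape_px: tuple[int, int],
    rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    radius_px = spec.eq_diameter_um / (2.0 * pixel_size_um)
    if radius_px < 1.0:
        raise ValueError(
            f"islet of {spec.eq_diameter_um} µm is below 2 px at "
            f"{pixel_size_um} µm/px"
        )
    if spec.shape == "disc":
        rr, cc = draw_disk(spec.center, radius_px, shape=shape_px)
    else:
        theta = np.linspace(0.0, 2.0 * math.pi, 180, endpoint=False)
        r = _blob_radii(radius_px, spec.irregularity, rng, len(theta))
        rows = spec.center[0] + r * np.sin(theta)
        cols = spec.center[1] + r * np.cos(theta)
        rr, cc = draw_polygon(rows, cols, shape=shape_px)
    return rr, cc


def make_scene(spec: SceneSpec) -> tuple[np.ndarray, LabelMask, list[TrueIslet]]:
    """Render one synthetic scene: RGB image, class mask, and ground truth.

    Non-embedded islets must not overlap (an error, since overlap would
    silently merge ground-truth objects); embedded islets get an exocrine
    annulus so their boundary is visually ambiguous, like islets fused with
    unstained tissue.
    """
    h, w = spec.shape_px
    rng = np.random.default_rng([spec.seed, 0])
    classes = np.zeros((h, w), dtype=np.int8)
    truths: list[TrueIslet] = []

    for islet in spec.islets:
        rr, cc = _islet_pixels(islet, spec.pixel_size_um, spec.shape_px, rng)
        if rr.size == 0:
            raise ValueError(f"islet at {islet.center} fell outside the image")
        overlap = classes[rr, cc] == TissueClass.ISLET
        if overlap.any() and not islet.embedded:
            raise ValueError(
                f"islet at {islet.center} overlaps an existing islet; "
                "only embedded islets may touch"
            )
        classes[rr, cc] = TissueClass.ISLET
        truths.append(
            TrueIslet(
                center=islet.center,
                eq_diameter_um=islet.eq_diameter_um,
                area_px=int(rr.size),
                embedded=islet.embedded,
            )
        )
        if islet.embedded:
            # Exocrine annulus: dilate and fill background ring pixels.
            blob = np.zeros((h, w), dtype=bool)
            blob[rr, cc] = True
            ring = ndimage.binary_dilation(blob, iterations=5) & ~blob
            classes[ring & (classes == TissueClass.BACKGROUND)] = TissueClass.EXOCRINE

    for _ in range(spec.n_exocrine_distractors):
        center = (int(rng.integers(0, h)), int(rng.integers(0, w)))
        radius = float(rng.uniform(4.0, 15.0))
        rr, cc = draw_disk(center, radius, shape=spec.shape_px)
        keep = classes[rr, cc] == TissueClass.BACKGROUND
        classes[rr[keep], cc[keep]] = TissueClass.EXOCRINE

    mask = LabelMask(classes=classes, encoding=dict(DEFAULT_ENCODING))
    image = _render_rgb(classes, rng)
    return image, mask, truths


def _render_rgb(classes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Cosmetic RGB rendering with mild brightness jitter."""
    h, w = classes.shape
    img = np.empty((h, w, 3), dtype=float)
    img[:] = _BACKGROUND_RGB
    img[classes == TissueClass.ISLET] = _ISLET_RGB
    img[classes == TissueClass.EXOCRINE] = _EXOCRINE_RGB
    img += rng.normal(0.0, 4.0, size=(h, w, 1))
    return np.clip(img, 0, 255).astype(np.uint8)


def make_template_lines(
    components: LabeledComponents,
    label: int,
    kind: str,
    rng: np.random.Generator,
    spacing_px: float = 2.0,
) -> Polyline:
    """Template line on one component: a separation chord or the contour.

    ``kind="CONTOUR"`` traces the component's boundary as a closed polyline
    resampled to roughly ``spacing_px`` vertex spacing (dense vertices make
    per-vertex jitter behave like independent pixel-scale noise).
    ``kind="SEPARATION"`` draws a straight chord through the centroid at a
    random angle, extended past the component so both endpoints lie outside
    it (trimming is then a meaningful step).
    """
    region = components.component_mask(label)
    if region.sum() < 3:
        raise ValueError(f"component {label} too small (<3 px) for a template")
    if kind == "CONTOUR":
        rings = measure.find_contours(region.astype(float), 0.5)
        ring = max(rings, key=len)
        pts = _resample(ring[:-1], spacing_px, closed=True)
        return Polyline(
            points=tuple(map(tuple, pts)), closed=True, role=LineRole.TEMPLATE
        )
    if kind == "SEPARATION":
        rows, cols = np.nonzero(region)
        centroid = np.array([rows.mean(), cols.mean()])
        theta = float(rng.uniform(0.0, math.pi))
        direction = np.array([math.sin(theta), math.cos(theta)])
        half = math.hypot(rows.max() - rows.min(), cols.max() - cols.min()) / 2.0 + 4.0
        a, b = centroid - half * direction, centroid + half * direction
        n = max(int(round(2 * half / spacing_px)), 2)
        t = np.linspace(0.0, 1.0, n + 1)[:, None]
        pts = a[None, :] * (1 - t) + b[None, :] * t
        return Polyline(
            points=tuple(map(tuple, pts)), closed=False, role=LineRole.TEMPLATE
        )
    raise ValueError(f"unknown template kind {kind!r}")


def _resample(points: np.ndarray, spacing: float, closed: bool) -> np.ndarray:
    """Resample a polyline to (approximately) uniform vertex spacing."""
    pts = np.asarray(points, dtype=float)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    n = max(int(round(total / spacing)), 4)
    targets = np.linspace(0.0, total, n, endpoint=False) if closed else np.linspace(
        0.0, total, n + 1
    )
    out = np.empty((len(targets), 2))
    out[:, 0] = np.interp(targets, arclen, pts[:, 0])
    out[:, 1] = np.interp(targets, arclen, pts[:, 1])
    return out


def simulate_expert_line(
    template: Polyline,
    profile: ExpertProfile,
    rng: np.random.Generator,
    smooth: bool = True,
) -> Polyline:
    """Displace each template vertex along its local normal by N(0, σ²).

    ``smooth`` applies a 3-point moving average afterwards, mimicking the
    low-pass character of finger/stylus drawing; disable it to obtain raw
    white jitter of exactly the requested σ.
    """
    pts = template.as_array()
    n = len(pts)
    if profile.jitter_sigma_px == 0.0:
        return Polyline(
            points=template.points,
            closed=template.closed,
            author=profile.expert_id,
            role=LineRole.EXPERT,
        )
    if template.closed:
        nxt, prv = np.roll(pts, -1, axis=0), np.roll(pts, 1, axis=0)
    else:
        nxt = np.vstack([pts[1:], pts[-1] + (pts[-1] - pts[-2])])
        prv = np.vstack([pts[0] - (pts[1] - pts[0]), pts[:-1]])
    tangent = nxt - prv
    norms = np.linalg.norm(tangent, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tangent /= norms
    normal = np.stack([-tangent[:, 1], tangent[:, 0]], axis=1)
    disp = rng.normal(0.0, profile.jitter_sigma_px, size=(n, 1))
    new = pts + disp * normal
    if smooth:
        if template.closed:
            new = (np.roll(new, 1, axis=0) + new + np.roll(new, -1, axis=0)) / 3.0
        else:
            inner = (new[:-2] + new[1:-1] + new[2:]) / 3.0
            new = np.vstack([new[:1], inner, new[-1:]])
    return Polyline(
        points=tuple(map(tuple, new)),
        closed=template.closed,
        author=profile.expert_id,
        role=LineRole.EXPERT,
    )


def simulate_opinions(
    manifest: SelectionManifest,
    profiles: Sequence[ExpertProfile],
    bundle: Bundle,
    seed: int = 0,
) -> list[ImageOpinion | IsletOpinion]:
    """One ImageOpinion per (expert, image), one IsletOpinion per marked islet.

    With probability ``p_false_call`` an expert disputes a contour and
    submits a FULL_REDRAW edit: a jittered tracing of that islet's boundary.
    """
    ops: list[ImageOpinion | IsletOpinion] = []
    comps = {e.image_id: label_islets(bundle.masks[e.image_id]) for e in manifest.entries}
    for profile in profiles:
        rng = np.random.default_rng([seed, profile.seed_offset, 1])
        for entry in manifest.entries:
            ops.append(
                ImageOpinion(
                    expert=profile.expert_id,
                    image=entry.image_id,
                    quality=Quality.GOOD,
                )
            )
            for pick in entry.islets:
                if rng.uniform() < profile.p_false_call:
                    template = make_template_lines(
                        comps[entry.image_id], pick.islet_label, "CONTOUR", rng
                    )
                    redraw = simulate_expert_line(template, profile, rng)
                    ops.append(
                        IsletOpinion(
                            expert=profile.expert_id,
                            image=entry.image_id,
                            islet=pick.set_islet_no,
                            verdict=Verdict.FALSE_CONTOUR,
                            edits=(GraphicalEdit(EditKind.FULL_REDRAW, redraw),),
                        )
                    )
                else:
                    ops.append(
                        IsletOpinion(
                            expert=profile.expert_id,
                            image=entry.image_id,
                            islet=pick.set_islet_no,
                            verdict=Verdict.TRUE_CONTOUR,
                        )
                    )
    return ops


def simulate_replicate_volumes(
    components: LabeledComponents,
    label: int,
    profiles: Sequence[ExpertProfile],
    pixel_size_um: float,
    n_replicates: int = 3,
    seed: int = 0,
) -> dict[str, list[float]]:
    """Replicate contour tracings of one islet, converted to IE volumes.

    Emulates a repeatability experiment: every expert re-traces the same
    islet ``n_replicates`` times and each tracing becomes a volume.
    """
    out: dict[str, list[float]] = {}
    for profile in profiles:
        rng = np.random.default_rng([seed, profile.seed_offset, 2])
        template = make_template_lines(components, label, "CONTOUR", rng)
        volumes = []
        for _ in range(n_replicates):
            traced = simulate_expert_line(template, profile, rng)
            volumes.append(contour_volume(traced, pixel_size_um))
        out[profile.expert_id] = volumes
    return out


def simulate_tracing_experiment(
    bundle: Bundle,
    n_templates: int,
    profiles: Sequence[ExpertProfile],
    seed: int = 0,
    kind: str = "SEPARATION",
    min_diameter_um: float = 80.0,
) -> tuple[list[tuple[str, str, Polyline]], list[tuple[str, str, Polyline]]]:
    """Template lines on bundle islets plus every expert's jittered tracing.

    Picks the ``n_templates`` largest islets (≥ ``min_diameter_um``) across
    the bundle, draws one template line of the requested kind on each, and
    has every profile trace every template.  Returns (templates,
    expert_lines) as (image, line_id, polyline) records ready for the CSV
    interchange format.
    """
    rng = np.random.default_rng([seed, 3])
    candidates: list[tuple[float, str, int]] = []
    for iid in sorted(bundle.masks):
        comps = label_islets(bundle.masks[iid])
        for rec in summarize_image(comps, bundle.pixel_sizes[iid]):
            if rec.eq_diameter_um >= min_diameter_um:
                candidates.append((rec.eq_diameter_um, iid, rec.islet_label))
    candidates.sort(reverse=True)
    if len(candidates) < n_templates:
        raise ValueError(
            f"bundle holds only {len(candidates)} islets ≥ {min_diameter_um} µm, "
            f"need {n_templates}"
        )
    comps_cache = {iid: label_islets(bundle.masks[iid]) for iid in bundle.masks}
    templates = []
    for k, (_, iid, label) in enumerate(candidates[:n_templates], start=1):
        line = make_template_lines(comps_cache[iid], label, kind, rng)
        templates.append((iid, f"t{k:02d}", line))
    expert_lines = []
    for profile in profiles:
        prof_rng = np.random.default_rng([seed, profile.seed_offset, 4])
        for iid, line_id, template in templates:
            expert_lines.append(
                (iid, line_id, simulate_expert_line(template, profile, prof_rng))
            )
    return templates, expert_lines


def random_scene_spec(
    seed: int,
    shape_px: tuple[int, int] = (512, 512),
    pixel_size_um: float | None = None,
    n_islets: tuple[int, int] = (6, 14),
    diameter_um: tuple[float, float] = (50.0, 400.0),
    p_blob: float = 0.7,
    p_embedded: float = 0.15,
) -> SceneSpec:
    """Draw a plausible scene layout: non-overlapping islets of mixed sizes.

    Pixel sizes default to the 1.41–3.77 µm/px range of typical islet-count
    micrographs; diameters span the 50–400 µm study range with a bias toward
    small islets (size distributions of isolated islets are right-skewed).
    """
    rng = np.random.default_rng([seed, 17])
    if pixel_size_um is None:
        pixel_size_um = float(rng.uniform(1.41, 3.77))
    h, w = shape_px
    n = int(rng.integers(n_islets[0], n_islets[1] + 1))
    placed: list[tuple[int, int, float]] = []  # (r, c, radius_px)
    specs = []
    for _ in range(n):
        # Right-skewed diameters: squared uniform keeps most islets small.
        u = rng.uniform() ** 2
        d_um = diameter_um[0] + u * (diameter_um[1] - diameter_um[0])
        radius_px = d_um / (2.0 * pixel_size_um)
        for _attempt in range(60):
            r = int(rng.integers(int(radius_px) + 6, max(h - int(radius_px) - 6, int(radius_px) + 7)))
            c = int(rng.integers(int(radius_px) + 6, max(w - int(radius_px) - 6, int(radius_px) + 7)))
            if all(
                math.hypot(r - pr, c - pc) > 1.35 * (radius_px + prad) + 8
                for pr, pc, prad in placed
            ):
                placed.append((r, c, radius_px))
                specs.append(
                    IsletSpec(
                        center=(r, c),
                        eq_diameter_um=float(d_um),
                        shape="blob" if rng.uniform() < p_blob else "disc",
                        irregularity=float(rng.uniform(0.08, 0.25)),
                        embedded=bool(rng.uniform() < p_embedded),
                    )
                )
                break
    return SceneSpec(
        shape_px=shape_px,
        pixel_size_um=pixel_size_um,
        islets=tuple(specs),
        n_exocrine_distractors=int(rng.integers(2, 6)),
        seed=seed,
    )


def make_bundle(
    out_dir: str | Path,
    n_images: int = 19,
    seed: int = 0,
    shape_px: tuple[int, int] = (512, 512),
) -> Bundle:
    """Write a complete engine-ready bundle: images/, masks/, pixel_sizes.csv.

    Also returns the bundle in memory.  Image ids are img01, img02, …
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    images: dict[str, np.ndarray] = {}
    masks: dict[str, LabelMask] = {}
    pixel_sizes: dict[str, float] = {}
    for i in range(1, n_images + 1):
        iid = f"img{i:02d}"
        spec = random_scene_spec(seed=seed * 1009 + i, shape_px=shape_px)
        image, mask, _ = make_scene(spec)
        images[iid], masks[iid] = image, mask
        pixel_sizes[iid] = spec.pixel_size_um
        write_image(image, out_dir / "images" / f"{iid}.png")
        write_mask(mask, out_dir / "masks" / f"{iid}.png")
    write_pixel_size_table(pixel_sizes, out_dir / "pixel_sizes.csv")
    return Bundle(images=images, masks=masks, pixel_sizes=pixel_sizes)
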