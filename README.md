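# isletkit

Morphometry, stratified review sampling and expert contour-agreement
metrics for microscopy of isolated pancreatic islets.

## The problem

Clinical islet transplantation ends with a graft quality-control step:
isolated islets are stained with dithizone, imaged, and quantified by
number, volume and size distribution.  The standard volume unit is the
**islet equivalent (IE / IEQ)** — the volume of a sphere 150 µm in
diameter.  From an islet's 2-D area *A* (µm²) in a segmentation mask, the
equivalent-circle diameter and spherical-model volume are

```
d = 2·√(A/π)          V = (d/150)³  [IE]
```

and islets are sorted into 50 µm diameter categories (50–100, 100–150, …).

Segmentation masks for these images are drawn by experts, and experts
disagree — especially on islets embedded in unstained exocrine tissue.
`isletkit` implements the computational machinery of an expert
contour-review workflow:

- **mask_io / morphometry** — read class-coded masks (islet / exocrine /
  background) and per-image pixel sizes, label islet objects, compute
  areas, equivalent diameters, size categories and IE volumes;
- **contours** — extract 1-px islet boundaries, render contour overlays,
  arrow-marked review images and per-islet crops;
- **selection** — the review-set engine: random images, then random islets
  drawn round-robin across the occupied 50 µm size categories above a size
  threshold, with reproducible per-set numbering;
- **line_metrics** — score an expert's tracing of a template line by the
  symmetric mean nearest-neighbour pixel distance after trimming to the
  islet mass (good if < 2 px), convert closed contours to IE volumes, and
  compute relative error `RE = |V_expert − V_template|/V_template` and
  replicate coefficients of variation;
- **opinions** — validate, tally and export expert opinions (image quality,
  True/False/skip contour verdicts, graphical edits) and render anonymized
  consensus reports;
- **usability** — System Usability Scale scoring and Sauro–Lewis curved
  grading;
- **synthetic** — scenes with known ground truth (discs and harmonic blobs
  of controlled equivalent diameter, exocrine distractors, embedded
  islets), template lines, and simulated experts with controlled
  perpendicular jitter, so the whole pipeline runs without any real data.

## Worked example

```sh
isletkit fixtures make --out bundle --n-images 19 --seed 5
isletkit select bundle --out review --n-images 8 --seed 7 --threshold-um 50
```

writes `review/manifest.csv` plus one arrow-marked PNG per selected image,
and reports on stderr:

```
selected 8 images / 52 islets (seed 7)
```

Scoring a usability questionnaire (per-expert scores in `expert,score`
rows):

```sh
isletkit sus responses.csv --out sus_scores.csv
# overall 86.0 (A+)
```

In Python, the spherical model and the tracing metric directly:

```python
>>> from isletkit import islet_volume_ie, equivalent_diameter
>>> islet_volume_ie(150.0), islet_volume_ie(75.0), islet_volume_ie(300.0)
(1.0, 0.125, 8.0)
>>> from isletkit import average_line_distance
>>> a = {(10, c) for c in range(50)}        # a 50 px template line
>>> average_line_distance(a, {(13, c) for c in range(50)})
3.0                                          # 3 px offset -> POOR (>= 2 px)
```

The other subcommands follow the same pattern: `accuracy` scores expert
tracings against template lines (one CSV row per tracing plus a median
summary row), `volumes` converts closed contours to IE volumes with RE and
replicate CV, and `consensus` renders per-disputed-islet report crops.

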