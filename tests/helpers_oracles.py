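"""Brute-force reference implementations used as independent test oracles.

Deliberately naive (per-pixel loops, BFS flood fill, all-pairs scans) so
they share no code path with the package implementations they check.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def flood_fill_label(islet: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    """BFS connected-component labeling of a boolean mask."""
    h, w = islet.shape
    if connectivity == 4:
        neigh = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    else:
        neigh = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    labels = np.zeros((h, w), dtype=int)
    current = 0
    for r0 in range(h):
        for c0 in range(w):
            if islet[r0, c0] and labels[r0, c0] == 0:
                current += 1
                queue = deque([(r0, c0)])
                labels[r0, c0] = current
                while queue:
                    r, c = queue.popleft()
                    for dr, dc in neigh:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and islet[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = current
                            queue.append((rr, cc))
    return labels, current


def boundary_oracle(labels: np.ndarray) -> dict[int, set[tuple[int, int]]]:
    """Per-pixel 4-neighbor inner-boundary check."""
    h, w = labels.shape
    out: dict[int, set[tuple[int, int]]] = {}
    for r in range(h):
        for c in range(w):
            lab = labels[r, c]
            if lab <= 0:
                continue
            on_boundary = False
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or labels[rr, cc] != lab:
                    on_boundary = True
                    break
            if on_boundary:
                out.setdefault(int(lab), set()).add((r, c))
    return out


def allpairs_mean_nn(a, b, symmetric: bool = True) -> float:
    """All-pairs brute-force symmetric mean nearest-neighbour distance."""
    a, b = list(set(a)), list(set(b))

    def directed(src, dst):
        total = 0.0
        for p in src:
            total += min(math.hypot(p[0] - q[0], p[1] - q[1]) for q in dst)
        return total / len(src)

    d = directed(a, b)
    if not symmetric:
        return d
    return (d + directed(b, a)) / 2.0


def dilate_oracle(pixels, radius: int, shape) -> set[tuple[int, int]]:
    """Brute-force dilation of a pixel set by a Euclidean disc."""
    out = set()
    h, w = shape
    for r, c in pixels:
        for dr in range(-radius, radius + 1):
            for dc in range(-radius, radius + 1):
                if dr * dr + dc * dc <= radius * radius:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w:
                        out.add((rr, cc))
    return out
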