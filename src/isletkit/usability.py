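"""System Usability Scale (SUS) scoring and curved-grade mapping.

The SUS questionnaire alternates positively and negatively worded items
(odd items positive, even negative), each answered on a 1–5 Likert scale.
The score contribution is item−1 for odd items and 5−item for even items;
the sum of contributions times 2.5 gives a 0–100 score.  Scores map to
letter marks via the Sauro–Lewis curved grading scale, in which the mean of
a large score corpus (≈68) sits at the C/D boundary region and A+ starts
at 84.1.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

#: Sauro–Lewis curved grading scale: (lower score bound, mark), descending.
#: Bins are closed at their lower bound; anything below 51.7 is an F.
CURVED_GRADE_BINS: tuple[tuple[float, str], ...] = (
    (84.1, "A+"),
    (80.8, "A"),
    (78.9, "A-"),
    (77.2, "B+"),
    (74.1, "B"),
    (72.6, "B-"),
    (71.1, "C+"),
    (65.0, "C"),
    (62.7, "C-"),
    (51.7, "D"),
    (0.0, "F"),
)


@dataclass(frozen=True)
class SusResult:
    score: float
    mark: str


def sus_score(items: Sequence[int]) -> float:
    """Score one 10-item SUS response on the 0–100 scale."""
    if len(items) != 10:
        raise ValueError(f"SUS has exactly 10 items, got {len(items)}")
    total = 0
    for i, item in enumerate(items, start=1):
        if not (isinstance(item, (int,)) and 1 <= item <= 5):
            raise ValueError(f"item {i} must be an integer in 1..5, got {item!r}")
        total += (item - 1) if i % 2 == 1 else (5 - item)
    return total * 2.5


def sus_grade(score: float) -> str:
    """Map a 0–100 SUS score to its curved-grading mark."""
    if not 0.0 <= score <= 100.0:
        raise ValueError(f"SUS score must be in 0..100, got {score}")
    for lower, mark in CURVED_GRADE_BINS:
        if score >= lower:
            return mark
    raise AssertionError("unreachable: bins cover [0, 100]")


def score_and_grade(items: Sequence[int]) -> SusResult:
    s = sus_score(items)
    return SusResult(score=s, mark=sus_grade(s))


@dataclass(frozen=True)
class CohortSummary:
    per_expert: tuple[tuple[str, float, str], ...]  # (expert, score, mark)
    mean_score: float  # exact arithmetic mean
    mean_score_display: float  # truncated to one decimal for reporting
    mean_mark: str


def cohort_summary(scores: Iterable[tuple[str, float]]) -> CohortSummary:
    """Per-expert marks and the cohort mean score.

    The displayed mean is truncated (not rounded) to one decimal, matching
    the convention of reporting SUS aggregates at the precision of the
    individual scores without overstating them; the exact mean is kept
    alongside.
    """
    pairs = list(scores)
    if not pairs:
        raise ValueError("cohort_summary requires at least one score")
    per_expert = tuple((e, float(s), sus_grade(float(s))) for e, s in pairs)
    mean = sum(s for _, s, _ in per_expert) / len(per_expert)
    display = math.floor(mean * 10.0 + 1e-9) / 10.0
    return CohortSummary(
        per_expert=per_expert,
        mean_score=mean,
        mean_score_display=display,
        mean_mark=sus_grade(display),
    )


def read_sus_csv(path: str | Path) -> list[tuple[str, float]]:
    """Read ``expert,i1..i10`` raw responses or ``expert,score`` rows.

    Malformed rows are reported with their line number.
    """
    out: list[tuple[str, float]] = []
    with open(Path(path), newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        raw = len(header) >= 11
        for rownum, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                if raw:
                    items = [int(v) for v in row[1:11]]
                    out.append((row[0], sus_score(items)))
                else:
                    out.append((row[0], float(row[1])))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path} row {rownum}: {exc}") from None
    return out


def write_sus_csv(summary: CohortSummary, path: str | Path) -> None:
    with open(Path(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["expert", "score", "mark"])
        for expert, score, mark in summary.per_expert:
            writer.writerow([expert, f"{score:.1f}", mark])
        writer.writerow(["OVERALL", f"{summary.mean_score_display:.1f}", summary.mean_mark])
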