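"""Six-area classification of (contrast, percent-correct) points.

The psychometric plane is partitioned into six areas that grade an
animal's contrast-sensitivity (CS) function:

* **A1** — high accuracy (>= 75% correct) at low contrast: good CS.
* **A2** — high accuracy only at high contrast: moderate CS.
* **A3/A4** — accuracy between 50% and 75% at low/high contrast:
  responses still reflect training but CS is weak.
* **A5/A6** — below-chance accuracy at low/high contrast: incorrect or
  random responding, i.e. weak training.

The low/high-contrast boundary is not fixed by theory; the default
splits the tested 10%-100% range at its midpoint (50% contrast) and is
configurable.  Boundary conventions: accuracy exactly 75 falls in the
upper band, exactly 50 in the weak-CS band, and a contrast exactly at
the split counts as low contrast.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = ["AreaLabel", "ClassificationRule", "classify_point", "band_summary"]

AREAS = ("A1", "A2", "A3", "A4", "A5", "A6")
BANDS = {
    "A1": "good_moderate", "A2": "good_moderate",
    "A3": "weak_cs", "A4": "weak_cs",
    "A5": "weak_training", "A6": "weak_training",
}


class ClassificationError(ValueError):
    """Out-of-range inputs or an invalid rule."""


@dataclass(frozen=True)
class AreaLabel:
    label: str  # A1..A6

    def __post_init__(self) -> None:
        if self.label not in AREAS:
            raise ClassificationError(f"unknown area {self.label!r}")

    @property
    def band(self) -> str:
        return BANDS[self.label]


@dataclass(frozen=True)
class ClassificationRule:
    """Boundaries of the six-area partition.

    ``contrast_split`` separates the low-contrast (A1/A3/A5) from the
    high-contrast (A2/A4/A6) column; ``upper_band_min_pc`` is the
    accuracy floor of the good/moderate band; chance is fixed at 50%
    by the two-choice task.
    """

    contrast_split: float = 0.5
    upper_band_min_pc: float = 75.0
    chance_pc: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 < self.contrast_split < 1.0:
            raise ClassificationError("contrast_split must be in (0, 1)")
        if not self.chance_pc < self.upper_band_min_pc <= 100.0:
            raise ClassificationError(
                "need chance_pc < upper_band_min_pc <= 100"
            )


def classify_point(
    contrast: float,
    percent_correct: float,
    rule: ClassificationRule = ClassificationRule(),
) -> AreaLabel:
    """Assign one (contrast, percent correct) point to its area.

    The partition is exhaustive and disjoint: every valid point maps
    to exactly one of A1-A6.
    """
    if not 0.0 <= contrast <= 1.0:
        raise ClassificationError(f"contrast must be in [0, 1], got {contrast}")
    if not 0.0 <= percent_correct <= 100.0:
        raise ClassificationError(
            f"percent_correct must be in [0, 100], got {percent_correct}"
        )
    low = contrast <= rule.contrast_split
    if percent_correct >= rule.upper_band_min_pc:
        return AreaLabel("A1" if low else "A2")
    if percent_correct >= rule.chance_pc:
        return AreaLabel("A3" if low else "A4")
    return AreaLabel("A5" if low else "A6")


def band_summary(
    points: Iterable[Sequence[float]],
    rule: ClassificationRule = ClassificationRule(),
) -> dict:
    """Count points per area and per band.

    ``points`` is an iterable of (contrast, percent_correct) pairs.
    Returns ``{"areas": {...}, "bands": {...}, "fractions": {...},
    "n": N}``; counts sum to the number of points.
    """
    pts = [(float(c), float(pc)) for c, pc in points]
    if not pts:
        raise ClassificationError("need at least one point")
    labels = [classify_point(c, pc, rule).label for c, pc in pts]
    area_counts = Counter(labels)
    band_counts = Counter(BANDS[lab] for lab in labels)
    n = len(pts)
    return {
        "n": n,
        "areas": {a: area_counts.get(a, 0) for a in AREAS},
        "bands": {b: band_counts.get(b, 0)
                  for b in ("good_moderate", "weak_cs", "weak_training")},
        "fractions": {b: band_counts.get(b, 0) / n
                      for b in ("good_moderate", "weak_cs", "weak_training")},
    }
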