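"""Ambulatory / non-ambulatory epoch classification by the acceleration ratio.

An epoch whose unfiltered-to-filtered synthetic-acceleration ratio exceeds the
cutoff (1.16, the published adult threshold, which also discriminates young
children's activities) is non-ambulatory; a ratio at or below the cutoff is
ambulatory. Epochs whose filtered channel fell below the sensor floor have no
ratio and are reported as a third class, "still"; for MET prediction they are
routed to the non-ambulatory equation, since sitting motionless is
non-ambulatory.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .signal import EpochFeatures

__all__ = [
    "ActivityClass",
    "CutoffSpec",
    "classify_epoch",
    "classify_epochs",
    "discrimination_table",
]

#: Published ratio cutoffs per population.
ADULT_CUTOFF = 1.16
ELEMENTARY_CUTOFF = 1.12


class ActivityClass(str, Enum):
    AMBULATORY = "ambulatory"
    NON_AMBULATORY = "non_ambulatory"
    STILL = "still"

    def __str__(self) -> str:  # so CSV cells read "ambulatory", not the repr
        return self.value


@dataclass(frozen=True)
class CutoffSpec:
    """Ratio threshold separating the two activity classes.

    The rule is strict: ratio > cutoff -> non-ambulatory; a ratio exactly at
    the cutoff is ambulatory.
    """

    cutoff: float = ADULT_CUTOFF
    population_tag: str = "adult"

    def __post_init__(self) -> None:
        if self.cutoff <= 1.0:
            raise ValueError(f"cutoff must exceed 1.0, got {self.cutoff}")


def classify_epoch(features: EpochFeatures, spec: CutoffSpec = CutoffSpec()) -> ActivityClass:
    """Classify one epoch from its ratio (None -> still)."""
    if features.ratio is None:
        return ActivityClass.STILL
    if features.ratio > spec.cutoff:
        return ActivityClass.NON_AMBULATORY
    return ActivityClass.AMBULATORY


def classify_epochs(
    epochs: Iterable[EpochFeatures], spec: CutoffSpec = CutoffSpec()
) -> list[ActivityClass]:
    return [classify_epoch(e, spec) for e in epochs]


def discrimination_table(
    epochs: Sequence[EpochFeatures], spec: CutoffSpec = CutoffSpec()
) -> pd.DataFrame:
    """Per-activity discrimination rates at the given cutoff.

    Returns one row per activity label with columns ``n``, ``pct_above``,
    ``pct_below`` and ``pct_still``. Still epochs (no ratio) count toward the
    non-ambulatory side (``pct_above``) and are additionally broken out in
    ``pct_still``, so ``pct_above + pct_below == 100`` per row.

    Every epoch must carry an ``activity_label``.
    """
    rows: dict[str, dict[str, int]] = {}
    for i, e in enumerate(epochs):
        if e.activity_label is None:
            raise ValueError(f"epoch at position {i} has no activity_label")
        tally = rows.setdefault(e.activity_label, {"n": 0, "above": 0, "below": 0, "still": 0})
        tally["n"] += 1
        cls = classify_epoch(e, spec)
        if cls is ActivityClass.AMBULATORY:
            tally["below"] += 1
        else:
            tally["above"] += 1
            if cls is ActivityClass.STILL:
                tally["still"] += 1
    if not rows:
        raise ValueError("no epochs supplied")
    records = [
        {
            "activity_label": label,
            "n": t["n"],
            "pct_above": 100.0 * t["above"] / t["n"],
            "pct_below": 100.0 * t["below"] / t["n"],
            "pct_still": 100.0 * t["still"] / t["n"],
        }
        for label, t in rows.items()
    ]
    return pd.DataFrame.from_records(records)
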