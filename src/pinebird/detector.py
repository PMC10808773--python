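"""Precision/recall evaluation of automated vocalization detectors.

Human-verified review segments yield true-positive, false-positive and
false-negative tallies for the detector's annotations; the headline
study-wide metrics are count-weighted (micro-averaged) over segments,
i.e. computed from pooled tallies, not averaged per-segment ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DetectorCounts:
    """Annotation tallies for one review segment (or a pooled set)."""

    tp: int
    fp: int
    fn: int
    segment_id: int | None = None

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer")


def precision(counts: DetectorCounts) -> float:
    """tp / (tp + fp); NaN sentinel when the detector made no detections."""
    denom = counts.tp + counts.fp
    if denom == 0:
        return math.nan
    return counts.tp / denom


def recall(counts: DetectorCounts) -> float:
    """tp / (tp + fn); NaN sentinel when no true events existed to recall."""
    denom = counts.tp + counts.fn
    if denom == 0:
        return math.nan
    return counts.tp / denom


def pool_counts(counts: Sequence[DetectorCounts] | Iterable[DetectorCounts]) -> DetectorCounts:
    """Elementwise-summed tallies across segments."""
    counts = list(counts)
    if not counts:
        raise ValueError("cannot pool an empty list of counts")
    return DetectorCounts(
        tp=sum(c.tp for c in counts),
        fp=sum(c.fp for c in counts),
        fn=sum(c.fn for c in counts),
    )


def counts_from_frame(annotations: pd.DataFrame) -> list[DetectorCounts]:
    """Per-segment tallies from the annotations.csv schema."""
    return [
        DetectorCounts(tp=int(r.tp), fp=int(r.fp), fn=int(r.fn), segment_id=int(r.segment_id))
        for r in annotations.itertuples(index=False)
    ]


def detector_metrics(annotations: pd.DataFrame) -> pd.DataFrame:
    """Pooled and per-segment precision/recall table.

    One 'pooled' row (the study-wide micro-averaged metrics) followed by
    one row per segment.
    """
    per_segment = counts_from_frame(annotations)
    pooled = pool_counts(per_segment)
    rows = [
        {
            "scope": "pooled",
            "tp": pooled.tp,
            "fp": pooled.fp,
            "fn": pooled.fn,
            "precision": precision(pooled),
            "recall": recall(pooled),
        }
    ]
    for c in per_segment:
        rows.append(
            {
                "scope": f"segment_{c.segment_id}",
                "tp": c.tp,
                "fp": c.fp,
                "fn": c.fn,
                "precision": precision(c),
                "recall": recall(c),
            }
        )
    return pd.DataFrame(rows)
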