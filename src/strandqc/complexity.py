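"""Apparent library complexity and sequencing-depth classification.

Apparent complexity is the fraction of uniquely mapped reads that occupy
distinct (chromosome, strand, 5'-coordinate) positions:

    complexity = n_distinct_positions / n_reads

It is an uncorrected ("apparent") ratio: it decreases both with PCR
over-duplication and, eventually, with sequencing depth, so depth is always
recorded alongside. No saturation-corrected estimator is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMetricError, ValidationError
from .tags import AlignedTags

__all__ = [
    "ComplexityStats",
    "library_complexity",
    "classify_complexity",
    "classify_depth",
    "DEPTH_THRESHOLDS",
]

#: Depth bin edges in uniquely mapped reads.
DEPTH_THRESHOLDS = (1_000_000, 5_000_000, 12_000_000, 24_000_000)

_DEPTH_BINS = ("<1M", "1-5M", "5-12M", "12-24M", ">=24M")


@dataclass(frozen=True)
class ComplexityStats:
    n_reads: int
    n_distinct_positions: int
    complexity: float
    complexity_class: str
    depth_bin: str
    depth_class: str


def classify_complexity(complexity: float) -> str:
    """Complexity class: ``high`` (>= 0.8), ``low`` (<= 0.5), else ``medium``.

    Both printed inclusive edges are honoured: exactly 0.8 is high and
    exactly 0.5 is low.
    """
    if not (0 < complexity <= 1):
        raise ValidationError(f"complexity must lie in (0, 1], got {complexity}")
    if complexity >= 0.8:
        return "high"
    if complexity <= 0.5:
        return "low"
    return "medium"


def classify_depth(n_reads: int) -> tuple[str, str]:
    """Depth bin (edges 1M/5M/12M/24M, left-closed) and verbal depth class.

    Libraries below 1 million reads are severely undersequenced; more than
    12 million is reasonably deep. The verbal rules take precedence at their
    stated edges, so exactly 12,000,000 reads falls in the ``12-24M`` bin
    but is classed ``moderate`` (not *more than* 12 million).
    """
    if n_reads < 0:
        raise ValidationError(f"n_reads must be >= 0, got {n_reads}")
    depth_bin = _DEPTH_BINS[int(np.searchsorted(DEPTH_THRESHOLDS, n_reads, side="right"))]
    if n_reads < 1_000_000:
        depth_class = "severely_undersequenced"
    elif n_reads < 5_000_000:
        depth_class = "shallow"
    elif n_reads <= 12_000_000:
        depth_class = "moderate"
    else:
        depth_class = "deep"
    return depth_bin, depth_class


def library_complexity(tags: AlignedTags) -> ComplexityStats:
    """Compute apparent complexity and the complexity/depth classes.

    A "position" is the (chromosome, strand, 5'-coordinate) triple, so
    sense and antisense stacks at the same base are counted separately.
    Deterministic and invariant to read order.
    """
    n_reads = tags.n_reads
    if n_reads == 0:
        raise UndefinedMetricError("library complexity undefined for an empty library")
    distinct = 0
    for strand_map in (tags.plus_positions, tags.minus_positions):
        for pos in strand_map.values():
            distinct += len(np.unique(pos))
    complexity = distinct / n_reads
    depth_bin, depth_class = classify_depth(n_reads)
    return ComplexityStats(
        n_reads=n_reads,
        n_distinct_positions=distinct,
        complexity=complexity,
        complexity_class=classify_complexity(complexity),
        depth_bin=depth_bin,
        depth_class=depth_class,
    )
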