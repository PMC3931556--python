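"""Per-library expectation rules and study-level aggregation.

A surveyed library is not judged only by its QC tag: control libraries and
ChIP experiments performed under conditions that abolish binding are
*expected* to show minimal read clustering, so a low score there is a
success of the assay, not a failure. This module encodes those expectation
rules, joins them with the measured metrics into :class:`QCRecord` bundles,
and aggregates records the way a survey reports them: full score
distributions, best replicate per factor/condition, and per-study score
maxima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .complexity import ComplexityStats
from .errors import UndefinedMetricError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "LibraryMetadata",
    "QCRecord",
    "expected_outcome",
    "outcome_consistent",
    "best_replicate_per_condition",
    "max_score_per_study",
    "score_distribution",
    "complexity_rsc_correlation",
    "read_metadata",
    "write_metadata",
]

DATASET_KINDS = ("chip", "input", "igg")
PERTURBATIONS = (
    "none",
    "knockout_of_target",
    "knockdown_of_target",
    "perturbation_of_other_factor",
    "unstimulated_inducible",
    "time_course",
)
QC_TAGS = (-2, -1, 0, 1, 2)


@dataclass(frozen=True)
class LibraryMetadata:
    library_id: str
    study_id: str
    target: str
    condition: str
    dataset_kind: str = "chip"
    perturbation: str = "none"
    author_claimed_success: bool | None = None  # None = unknown

    def __post_init__(self) -> None:
        if self.dataset_kind not in DATASET_KINDS:
            raise ValidationError(
                f"dataset_kind {self.dataset_kind!r} not in {DATASET_KINDS}"
            )
        if self.perturbation not in PERTURBATIONS:
            raise ValidationError(
                f"perturbation {self.perturbation!r} not in {PERTURBATIONS}"
            )


@dataclass
class QCRecord:
    """One library's bundle of metadata, metrics and expectation."""

    library_id: str
    metadata: LibraryMetadata
    qc_tag: int
    rsc: float | None = None
    nsc: float | None = None
    fragment_peak_shift: int | None = None
    flags: frozenset[str] = frozenset()
    complexity_stats: ComplexityStats | None = None
    expectation: str | None = None  # expected_high / expected_low / unknown

    @property
    def complexity(self) -> float | None:
        return self.complexity_stats.complexity if self.complexity_stats else None

    @property
    def n_reads(self) -> int | None:
        return self.complexity_stats.n_reads if self.complexity_stats else None


def expected_outcome(metadata: LibraryMetadata) -> str:
    """Map library metadata to an expected QC outcome.

    Rules are evaluated in a fixed order; control status (input/IgG)
    dominates the perturbation fields:

    1. input or IgG control            -> expected_low
    2. knockout of the assayed factor  -> expected_low
    3. knockdown of the assayed factor -> unknown
    4. inducible factor, unstimulated  -> unknown
    5. perturbation of another factor, or a time course -> unknown
    6. anything else                   -> expected_high
    """
    if metadata.dataset_kind in ("input", "igg"):
        return "expected_low"
    p = metadata.perturbation
    if p == "knockout_of_target":
        return "expected_low"
    if p in ("knockdown_of_target", "unstimulated_inducible",
             "perturbation_of_other_factor", "time_course"):
        return "unknown"
    return "expected_high"


def outcome_consistent(expectation: str, qc_tag: int) -> bool | None:
    """Whether the observed tag matches the expectation.

    expected_high is consistent with tags {+1, +2}; expected_low with
    {-2, -1}; for an unknown expectation consistency is not applicable
    (returns None).
    """
    if expectation == "unknown":
        return None
    if expectation == "expected_high":
        return qc_tag >= 1
    if expectation == "expected_low":
        return qc_tag <= -1
    raise ValidationError(f"unknown expectation {expectation!r}")


def best_replicate_per_condition(records: Sequence[QCRecord]) -> list[QCRecord]:
    """One record per (study, target, condition) group: the maximal-RSC
    replicate, ties broken by higher read count, then lexicographically
    smallest library_id."""
    groups: dict[tuple[str, str, str], QCRecord] = {}
    for rec in records:
        key = (rec.metadata.study_id, rec.metadata.target, rec.metadata.condition)
        cur = groups.get(key)
        if cur is None or _replicate_rank(rec) > _replicate_rank(cur):
            groups[key] = rec
    return [groups[k] for k in sorted(groups)]


def _replicate_rank(rec: QCRecord) -> tuple:
    rsc = rec.rsc if rec.rsc is not None else float("-inf")
    n = rec.n_reads if rec.n_reads is not None else -1
    return (rsc, n, _ReversedStr(rec.library_id))


class _ReversedStr(str):
    """Orders lexicographically *smaller* strings as larger (for max-style
    tie-breaks that must prefer the smaller library_id)."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def max_score_per_study(
    records: Sequence[QCRecord], kinds: Iterable[str] = ("chip",)
) -> dict[str, int]:
    """Per-study maximum QC tag over records of the requested dataset kinds.

    Studies with no record of a requested kind are omitted with a logged
    notice.
    """
    kinds = set(kinds)
    out: dict[str, int] = {}
    seen_studies = {rec.metadata.study_id for rec in records}
    for rec in records:
        if rec.metadata.dataset_kind not in kinds:
            continue
        sid = rec.metadata.study_id
        out[sid] = max(out.get(sid, -2 - 1), rec.qc_tag)
    for sid in sorted(seen_studies - set(out)):
        logger.info("study %s omitted: no records of kinds %s", sid, sorted(kinds))
    return out


def score_distribution(
    records: Sequence[QCRecord], grouping: str = "none"
) -> pd.DataFrame:
    """Counts and fractions per QC tag, optionally grouped.

    Parameters
    ----------
    grouping
        ``none`` (single row), ``by_kind`` (chip/input/igg) or
        ``by_expectation``.

    Returns a DataFrame indexed by group with columns ``n``, per-tag counts
    (``count_-2`` ... ``count_+2``), per-tag fractions, and aggregate
    fractions ``frac_high`` (+1/+2), ``frac_intermediate`` (0) and
    ``frac_low`` (-2/-1).
    """
    if not records:
        raise UndefinedMetricError("score distribution undefined for no records")
    if grouping == "none":
        keyfn = lambda rec: "all"
    elif grouping == "by_kind":
        keyfn = lambda rec: rec.metadata.dataset_kind
    elif grouping == "by_expectation":
        keyfn = lambda rec: rec.expectation or "unknown"
    else:
        raise ValidationError(f"unknown grouping {grouping!r}")

    rows = {}
    for rec in records:
        key = keyfn(rec)
        counts = rows.setdefault(key, dict.fromkeys(QC_TAGS, 0))
        if rec.qc_tag not in counts:
            raise ValidationError(f"QC tag {rec.qc_tag} outside -2..+2")
        counts[rec.qc_tag] += 1

    table = []
    for key in sorted(rows):
        counts = rows[key]
        n = sum(counts.values())
        row = {"group": key, "n": n}
        for tag in QC_TAGS:
            row[f"count_{tag:+d}"] = counts[tag]
        for tag in QC_TAGS:
            row[f"frac_{tag:+d}"] = counts[tag] / n
        row["frac_high"] = (counts[1] + counts[2]) / n
        row["frac_intermediate"] = counts[0] / n
        row["frac_low"] = (counts[-2] + counts[-1]) / n
        table.append(row)
    return pd.DataFrame(table).set_index("group")


def complexity_rsc_correlation(records: Sequence[QCRecord]) -> float:
    """Pearson correlation between library complexity and RSC across a
    cohort (a diagnostic for duplication-driven cross-correlation
    artifacts)."""
    pairs = [
        (rec.complexity, rec.rsc)
        for rec in records
        if rec.complexity is not None
        and rec.rsc is not None
        and np.isfinite(rec.complexity)
        and np.isfinite(rec.rsc)
    ]
    if len(pairs) < 3:
        raise UndefinedMetricError(
            f"need >= 3 records with finite complexity and RSC, got {len(pairs)}"
        )
    x, y = np.asarray(pairs, dtype=float).T
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("correlation undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


_META_COLUMNS = [
    "library_id",
    "study_id",
    "target",
    "condition",
    "dataset_kind",
    "perturbation",
    "author_claimed_success",
]


def read_metadata(path: str | Path) -> list[LibraryMetadata]:
    """Read a library-metadata TSV (header row naming the fields)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _META_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing metadata columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        claimed_raw = str(getattr(row, "author_claimed_success", "")).strip().lower()
        claimed = {"true": True, "1": True, "yes": True,
                   "false": False, "0": False, "no": False}.get(claimed_raw)
        out.append(
            LibraryMetadata(
                library_id=row.library_id,
                study_id=row.study_id,
                target=row.target,
                condition=row.condition,
                dataset_kind=row.dataset_kind or "chip",
                perturbation=getattr(row, "perturbation", "") or "none",
                author_claimed_success=claimed,
            )
        )
    return out


def write_metadata(metadata: Sequence[LibraryMetadata], path: str | Path) -> None:
    rows = []
    for m in metadata:
        claimed = "" if m.author_claimed_success is None else str(m.author_claimed_success).lower()
        rows.append(
            {
                "library_id": m.library_id,
                "study_id": m.study_id,
                "target": m.target,
                "condition": m.condition,
                "dataset_kind": m.dataset_kind,
                "perturbation": m.perturbation,
                "author_claimed_success": claimed,
            }
        )
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)
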