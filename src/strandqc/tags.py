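"""Strand-separated aligned-read representation and tagAlign/BED/BAM I/O.

All downstream metrics operate on the 5' ends ("tags") of uniquely mapped
reads, kept per chromosome and per strand. Coordinates are 0-based; the tag
of a plus-strand read is its leftmost reference base, the tag of a
minus-strand read is its rightmost reference base (BED ``end - 1``).
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, UndefinedMetricError, ValidationError

__all__ = ["AlignedTags", "read_alignments", "write_tagalign", "read_chrom_sizes"]


@dataclass
class AlignedTags:
    """Per-chromosome, strand-separated 5'-end coordinates of uniquely
    mapped reads.

    Parameters
    ----------
    chrom_sizes
        Chromosome name -> length in bp.
    plus_positions, minus_positions
        Chromosome -> sorted int64 array of 5'-end coordinates (0-based).
        Duplicate coordinates are retained; de-duplication is a metric-level
        concern, never silent I/O behaviour.
    read_length
        Modal read length of the library, bp (>= 1).
    """

    chrom_sizes: dict[str, int]
    plus_positions: dict[str, np.ndarray] = field(default_factory=dict)
    minus_positions: dict[str, np.ndarray] = field(default_factory=dict)
    read_length: int = 1

    def __post_init__(self) -> None:
        for strand_map in (self.plus_positions, self.minus_positions):
            for chrom, pos in strand_map.items():
                strand_map[chrom] = np.asarray(pos, dtype=np.int64)

    @property
    def n_reads(self) -> int:
        """Total uniquely mapped reads (sum of both strands)."""
        return sum(len(v) for v in self.plus_positions.values()) + sum(
            len(v) for v in self.minus_positions.values()
        )

    def strand_counts(self) -> tuple[int, int]:
        """(plus, minus) genome-wide read counts."""
        return (
            sum(len(v) for v in self.plus_positions.values()),
            sum(len(v) for v in self.minus_positions.values()),
        )

    def chromosomes(self) -> list[str]:
        return sorted(self.chrom_sizes)

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any violated invariant."""
        if self.read_length < 1:
            raise ValidationError(f"read_length must be >= 1, got {self.read_length}")
        for label, strand_map in (("+", self.plus_positions), ("-", self.minus_positions)):
            for chrom, pos in strand_map.items():
                if chrom not in self.chrom_sizes:
                    raise ValidationError(f"unknown chromosome {chrom!r} on strand {label}")
                size = self.chrom_sizes[chrom]
                if len(pos) and (pos[0] < 0 or pos[-1] >= size):
                    raise ValidationError(
                        f"coordinate out of bounds on {chrom}{label}: "
                        f"range [{pos[0]}, {pos[-1]}] vs chromosome size {size}"
                    )
                if len(pos) > 1 and np.any(np.diff(pos) < 0):
                    raise ValidationError(f"positions not sorted on {chrom}{label}")

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, int, str]],
        chrom_sizes: Mapping[str, int],
        read_length: int,
    ) -> "AlignedTags":
        """Build from an iterable of (chrom, tag_position, strand) records."""
        plus: dict[str, list[int]] = collections.defaultdict(list)
        minus: dict[str, list[int]] = collections.defaultdict(list)
        for chrom, pos, strand in records:
            (plus if strand == "+" else minus)[chrom].append(pos)
        return cls(
            chrom_sizes=dict(chrom_sizes),
            plus_positions={c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in plus.items()},
            minus_positions={c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in minus.items()},
            read_length=read_length,
        )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``name<TAB>length`` chromosome-sizes file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}: line {i}: expected 'name<TAB>length'")
            sizes[parts[0]] = int(parts[1])
    return sizes


def _modal_length(lengths: np.ndarray) -> int:
    """Most common value; ties broken toward the smaller length."""
    values, counts = np.unique(lengths, return_counts=True)
    return int(values[np.argmax(counts)])


def _read_bed_like(
    path: str | Path, chrom_sizes: Mapping[str, int] | None
) -> AlignedTags:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2, 5],
            names=["chrom", "start", "end", "strand"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "strand"])
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: not parseable as tagAlign/BED6: {exc}") from exc

    if len(df):
        bad = ~df["strand"].isin(["+", "-"])
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: record {i + 1} has strand {df['strand'].iloc[i]!r} (need '+' or '-')"
            )
        if (df["end"] <= df["start"]).any():
            i = int(np.flatnonzero((df["end"] <= df["start"]).to_numpy())[0])
            raise FormatError(f"{path}: record {i + 1} has end <= start")

    if chrom_sizes is None:
        # infer minimal sizes from the data itself
        chrom_sizes = (
            df.groupby("chrom")["end"].max().astype(int).to_dict() if len(df) else {}
        )
    else:
        chrom_sizes = dict(chrom_sizes)
        for i, row in enumerate(df.itertuples(index=False), 1):
            size = chrom_sizes.get(row.chrom)
            if size is None or row.end > size:
                raise ValidationError(
                    f"{path}: record {i} ({row.chrom}:{row.start}-{row.end}) "
                    f"exceeds chromosome size {size}"
                )

    if not len(df):
        return AlignedTags(chrom_sizes=dict(chrom_sizes), read_length=1)

    read_length = _modal_length((df["end"] - df["start"]).to_numpy())
    tag = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    recs = zip(df["chrom"], tag.astype(int), df["strand"])
    return AlignedTags.from_records(recs, chrom_sizes, read_length)


def _read_bam(
    path: str | Path, chrom_sizes: Mapping[str, int] | None, min_mapq: int
) -> AlignedTags:
    import pysam

    records: list[tuple[str, int, str]] = []
    lengths: list[int] = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        header_sizes = {r: l for r, l in zip(bam.references, bam.lengths)}
        sizes = dict(chrom_sizes) if chrom_sizes is not None else header_sizes
        for rec in bam.fetch(until_eof=True):
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or rec.is_duplicate
            ):
                continue
            if min_mapq and rec.mapping_quality < min_mapq:
                continue
            chrom = rec.reference_name
            size = sizes.get(chrom)
            if size is None or rec.reference_end > size:
                raise ValidationError(
                    f"{path}: read {rec.query_name!r} at {chrom}:{rec.reference_start} "
                    f"exceeds chromosome size {size}"
                )
            if rec.is_reverse:
                records.append((chrom, rec.reference_end - 1, "-"))
            else:
                records.append((chrom, rec.reference_start, "+"))
            qlen = rec.query_length or rec.infer_read_length() or 0
            if qlen:
                lengths.append(qlen)

    if not records:
        return AlignedTags(chrom_sizes=sizes, read_length=1)
    read_length = _modal_length(np.asarray(lengths)) if lengths else 1
    return AlignedTags.from_records(records, sizes, read_length)


def read_alignments(
    path: str | Path,
    format: str = "tagalign",
    chrom_sizes: Mapping[str, int] | None = None,
    min_mapq: int = 0,
) -> AlignedTags:
    """Read aligned reads into the strand-separated tag representation.

    Parameters
    ----------
    format
        One of ``tagalign``, ``bed`` (both BED6 text) or ``bam``.
    chrom_sizes
        Optional chromosome-size map; required to validate BED coordinates
        against a genome (otherwise sizes are inferred from the data). For
        BAM, defaults to the header.
    min_mapq
        Optional MAPQ threshold for BAM input (0 = off). Uniqueness of
        mapping is otherwise taken at face value from the input file.

    Records flagged unmapped, secondary, supplementary or duplicate by the
    aligner are excluded. ``read_length`` is set to the modal record length.
    """
    fmt = format.lower()
    if fmt in ("tagalign", "bed"):
        return _read_bed_like(path, chrom_sizes)
    if fmt == "bam":
        return _read_bam(path, chrom_sizes, min_mapq)
    raise FormatError(f"unknown alignment format {format!r} (use tagalign, bed or bam)")


def write_tagalign(tags: AlignedTags, path: str | Path) -> None:
    """Write tags as tagAlign/BED6; round-trips exactly through
    :func:`read_alignments`.

    Plus-strand tags are written as ``[pos, pos + read_length)``; minus-strand
    tags as ``[pos + 1 - read_length, pos + 1)`` (start clamped at 0 near the
    chromosome edge -- the 5' coordinate, held by ``end - 1``, is preserved
    regardless).
    """
    rl = tags.read_length
    with open(path, "w") as fh:
        i = 0
        for chrom in tags.chromosomes():
            rows: list[tuple[int, int, str]] = []
            for pos in tags.plus_positions.get(chrom, ()):
                rows.append((int(pos), int(pos) + rl, "+"))
            for pos in tags.minus_positions.get(chrom, ()):
                rows.append((max(0, int(pos) + 1 - rl), int(pos) + 1, "-"))
            rows.sort()
            for start, end, strand in rows:
                i += 1
                fh.write(f"{chrom}\t{start}\t{end}\tr{i}\t0\t{strand}\n")


def subsample(tags: AlignedTags, n: int, seed: int) -> AlignedTags:
    """Uniform random subsample of ``n`` reads without replacement."""
    total = tags.n_reads
    if n > total:
        raise UndefinedMetricError(f"cannot subsample {n} reads from {total}")
    rng = np.random.default_rng(seed)
    keep = np.zeros(total, dtype=bool)
    keep[rng.choice(total, size=n, replace=False)] = True
    out_plus: dict[str, np.ndarray] = {}
    out_minus: dict[str, np.ndarray] = {}
    offset = 0
    for strand_map, out in ((tags.plus_positions, out_plus), (tags.minus_positions, out_minus)):
        for chrom in sorted(strand_map):
            pos = strand_map[chrom]
            out[chrom] = pos[keep[offset : offset + len(pos)]]
            offset += len(pos)
    return AlignedTags(
        chrom_sizes=dict(tags.chrom_sizes),
        plus_positions=out_plus,
        minus_positions=out_minus,
        read_length=tags.read_length,
    )
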