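"""Independent brute-force oracles used by multiple test modules.

These stay deliberately naive: dense per-base count vectors, textbook
Pearson via np.corrcoef, all-pairs overlap scans. They must never share
code with the package implementation they check.
"""

import numpy as np

from strandqc import AlignedTags, QCRecord, LibraryMetadata, ComplexityStats


def brute_force_profile(tags: AlignedTags, shifts) -> np.ndarray:
    """Dense-vector cross-correlation: materialize per-base counts, call
    np.corrcoef per chromosome, combine with (length - shift) weights.
    Chromosomes with an empty strand are skipped, as in the engine."""
    shifts = np.asarray(shifts)
    num = np.zeros(len(shifts))
    den = np.zeros(len(shifts))
    for chrom, length in tags.chrom_sizes.items():
        p_pos = tags.plus_positions.get(chrom, [])
        m_pos = tags.minus_positions.get(chrom, [])
        if len(p_pos) == 0 or len(m_pos) == 0:
            continue
        p = np.bincount(p_pos, minlength=length)[:length].astype(float)
        m = np.bincount(m_pos, minlength=length)[:length].astype(float)
        for k, d in enumerate(shifts):
            x = p[: length - d]
            y = m[d:length]
            if x.std() == 0 or y.std() == 0:
                continue
            num[k] += (length - d) * np.corrcoef(x, y)[0, 1]
            den[k] += length - d
    return np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)


def brute_force_overlap(peaks_a, peaks_b, window):
    """All-pairs sharedness counts."""
    def shared(src, other):
        n = 0
        for p in src:
            if any(q.chrom == p.chrom and abs(q.summit - p.summit) <= window for q in other):
                n += 1
        return n

    return shared(peaks_a, peaks_b), shared(peaks_b, peaks_a)


def make_record(
    library_id,
    study_id="s1",
    target="TF1",
    condition="c1",
    dataset_kind="chip",
    perturbation="none",
    qc_tag=2,
    rsc=2.0,
    n_reads=1_000_000,
    complexity=0.9,
    expectation=None,
) -> QCRecord:
    meta = LibraryMetadata(
        library_id=library_id,
        study_id=study_id,
        target=target,
        condition=condition,
        dataset_kind=dataset_kind,
        perturbation=perturbation,
    )
    stats = ComplexityStats(
        n_reads=n_reads,
        n_distinct_positions=int(round(complexity * n_reads)),
        complexity=complexity,
        complexity_class="high",
        depth_bin="<1M",
        depth_class="severely_undersequenced",
    )
    return QCRecord(
        library_id=library_id,
        metadata=meta,
        qc_tag=qc_tag,
        rsc=rsc,
        complexity_stats=stats,
        expectation=expectation,
    )
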