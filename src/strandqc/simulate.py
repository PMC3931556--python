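"""Synthetic aligned-tag libraries with ChIP-seq statistical structure.

The generator produces exactly the features the QC metrics respond to,
without any sequence-level simulation:

* **Point-source signal** -- binding sites emit fragments centred on the
  site; each fragment is sequenced from one end (fair coin), so plus-strand
  tags pile up a half fragment upstream and minus-strand tags a half
  fragment downstream of the site. This is the strand-asymmetric clustering
  that creates the fragment-length cross-correlation peak.
* **Sono-seq-like control enrichment** -- open-chromatin regions emit the
  same two-ended fragments, but centred anywhere within the region. The
  clustering is weaker and broader than true point-source signal, yet still
  produces a fragment-length peak: the mechanism by which control libraries
  can score like successful ChIP.
* **Uniform background** with a read-stacking component: a fraction of
  background reads is drawn from a finite pool of "anchor" positions that
  stack plus reads at ``a`` and minus reads at ``a + read_length``. Real
  libraries always carry this read-length ("phantom") artifact -- it arises
  from mappability structure -- and the RSC metric is defined relative to
  it, so the generator reproduces it explicitly.
* **PCR duplication** -- each tag receives a Poisson number of extra copies.

Everything is fully determined by the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .cohort import LibraryMetadata, write_metadata
from .errors import ValidationError
from .tags import AlignedTags, write_tagalign

__all__ = ["SimulationConfig", "simulate_library", "apply_pcr_duplication", "simulate_cohort"]

_MAX_REDRAWS = 100


def _default_chrom_sizes() -> dict[str, int]:
    return {"chr1": 10_000_000}


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a synthetic library.

    Fractions partition reads into signal / Sono-seq / background
    components (``signal_fraction + sono_fraction <= 1``); ``anchor_*``
    parameters control the read-stacking artifact inside the background
    component (see module docstring).
    """

    chrom_sizes: dict[str, int] = field(default_factory=_default_chrom_sizes)
    n_sites: int = 10_000
    site_positions: tuple[tuple[str, int], ...] | None = None
    signal_fraction: float = 0.4
    fragment_length_mean: int = 200
    fragment_length_sd: int = 20
    read_length: int = 36
    n_reads: int = 500_000
    sono_regions: int = 2_000
    sono_region_width: int = 600
    sono_fraction: float = 0.0
    anchor_sites: int = 100_000
    anchor_fraction: float = 0.1
    duplication_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("signal_fraction", "sono_fraction", "anchor_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.signal_fraction + self.sono_fraction > 1 + 1e-12:
            raise ValidationError("signal_fraction + sono_fraction must be <= 1")
        for name in ("fragment_length_mean", "read_length", "sono_region_width", "n_reads"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.fragment_length_sd < 0 or self.duplication_rate < 0:
            raise ValidationError("fragment_length_sd and duplication_rate must be >= 0")
        if not self.chrom_sizes:
            raise ValidationError("chrom_sizes must not be empty")


def _draw_fragment_lengths(
    rng: np.random.Generator, n: int, mean: int, sd: int, lo: int, hi: int
) -> np.ndarray:
    """Normal(mean, sd) truncated to [lo, hi] by rejection, rounded to int."""
    if sd == 0:
        return np.full(n, int(round(mean)), dtype=np.int64)
    out = rng.normal(mean, sd, size=n)
    for _ in range(_MAX_REDRAWS):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    else:
        raise ValidationError(
            f"could not draw fragment lengths in [{lo}, {hi}] "
            f"from Normal({mean}, {sd})"
        )
    return np.rint(out).astype(np.int64)


def _fragment_tags(
    rng: np.random.Generator,
    centers: np.ndarray,
    lengths_bp: np.ndarray,
    cfg: SimulationConfig,
    redraw_centers=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Tags for fragments centred at ``centers`` on chromosomes of size
    ``lengths_bp``: draw F, place fragment [c - F//2, c - F//2 + F), emit a
    plus tag at its left end or a minus tag at its right end (fair coin).
    Infeasible geometry (fragment off the chromosome edge) redraws the
    fragment (and the centre, if ``redraw_centers`` is given), with an
    iteration cap."""
    n = len(centers)
    lo, hi = cfg.read_length, 2 * cfg.fragment_length_mean
    frag = _draw_fragment_lengths(rng, n, cfg.fragment_length_mean, cfg.fragment_length_sd, lo, hi)
    left = centers - frag // 2
    for _ in range(_MAX_REDRAWS):
        bad = (left < 0) | (left + frag > lengths_bp)
        if not bad.any():
            break
        nb = int(bad.sum())
        if redraw_centers is not None:
            centers = centers.copy()
            centers[bad] = redraw_centers(rng, bad)
        frag[bad] = _draw_fragment_lengths(
            rng, nb, cfg.fragment_length_mean, cfg.fragment_length_sd, lo, hi
        )
        left = centers - frag // 2
    else:
        raise ValidationError(
            "fragment placement infeasible after redraws "
            "(site too close to a chromosome edge?)"
        )
    is_plus = rng.random(n) < 0.5
    pos = np.where(is_plus, left, left + frag - 1)
    return pos, is_plus


def simulate_library(
    config: SimulationConfig,
) -> tuple[AlignedTags, dict]:
    """Generate one library.

    Returns the tags plus a truth bundle: ``sites`` and ``sono_regions``
    DataFrames, and ``reads`` -- one row per read with chromosome, strand,
    position, origin label (signal/sono/background) and whether it came
    from an anchor stack.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = sorted(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in names], dtype=np.int64)
    weights = sizes / sizes.sum()

    margin = 2 * config.fragment_length_mean

    # --- binding sites
    if config.site_positions is not None:
        site_chrom = np.array([names.index(c) for c, _ in config.site_positions])
        site_pos = np.array([p for _, p in config.site_positions], dtype=np.int64)
    else:
        site_chrom = rng.choice(len(names), size=config.n_sites, p=weights)
        span = np.maximum(sizes[site_chrom] - 2 * margin, 1)
        site_pos = margin + (rng.random(config.n_sites) * span).astype(np.int64)

    # --- sono regions (starts)
    sono_chrom = rng.choice(len(names), size=config.sono_regions, p=weights)
    sono_span = np.maximum(sizes[sono_chrom] - config.sono_region_width - 2 * margin, 1)
    sono_start = margin + (rng.random(config.sono_regions) * sono_span).astype(np.int64)

    # --- anchor positions (read-stacking artifact)
    anchor_chrom = rng.choice(len(names), size=config.anchor_sites, p=weights)
    anchor_pos = (
        rng.random(config.anchor_sites)
        * np.maximum(sizes[anchor_chrom] - config.read_length - 1, 1)
    ).astype(np.int64)

    # --- per-read origin
    p_bg = 1.0 - config.signal_fraction - config.sono_fraction
    origin = rng.choice(
        3, size=config.n_reads, p=[config.signal_fraction, config.sono_fraction, max(p_bg, 0.0)]
    )
    n_sig = int((origin == 0).sum())
    n_sono = int((origin == 1).sum())
    n_bg = int((origin == 2).sum())

    chrom_idx = np.empty(config.n_reads, dtype=np.int64)
    pos = np.empty(config.n_reads, dtype=np.int64)
    is_plus = np.empty(config.n_reads, dtype=bool)
    is_anchor = np.zeros(config.n_reads, dtype=bool)

    # signal reads
    if n_sig:
        if len(site_pos) == 0:
            raise ValidationError("signal_fraction > 0 requires binding sites")
        pick = rng.integers(0, len(site_pos), size=n_sig)
        ci = site_chrom[pick]
        p, s = _fragment_tags(rng, site_pos[pick].copy(), sizes[ci], config)
        sel = origin == 0
        chrom_idx[sel], pos[sel], is_plus[sel] = ci, p, s

    # sono reads
    if n_sono:
        if config.sono_regions == 0:
            raise ValidationError("sono_fraction > 0 requires sono regions")
        pick = rng.integers(0, config.sono_regions, size=n_sono)
        ci = sono_chrom[pick]
        centers = sono_start[pick] + rng.integers(0, config.sono_region_width, size=n_sono)

        def redraw(rng_, bad):
            p2 = rng.integers(0, config.sono_region_width, size=int(bad.sum()))
            return sono_start[pick[bad]] + p2

        p, s = _fragment_tags(rng, centers, sizes[ci], config, redraw_centers=redraw)
        sel = origin == 1
        chrom_idx[sel], pos[sel], is_plus[sel] = ci, p, s

    # background reads
    if n_bg:
        anchored = rng.random(n_bg) < config.anchor_fraction
        n_anc = int(anchored.sum())
        bp = np.empty(n_bg, dtype=np.int64)
        bc = np.empty(n_bg, dtype=np.int64)
        bs = rng.random(n_bg) < 0.5
        if n_anc:
            pick = rng.integers(0, config.anchor_sites, size=n_anc)
            bc[anchored] = anchor_chrom[pick]
            bp[anchored] = np.where(
                bs[anchored], anchor_pos[pick], anchor_pos[pick] + config.read_length
            )
        n_uni = n_bg - n_anc
        if n_uni:
            ci = rng.choice(len(names), size=n_uni, p=weights)
            bc[~anchored] = ci
            bp[~anchored] = (rng.random(n_uni) * sizes[ci]).astype(np.int64)
        sel = origin == 2
        chrom_idx[sel], pos[sel], is_plus[sel] = bc, bp, bs
        is_anchor[sel] = anchored

    plus_map: dict[str, np.ndarray] = {}
    minus_map: dict[str, np.ndarray] = {}
    for i, name in enumerate(names):
        mask = chrom_idx == i
        plus_map[name] = np.sort(pos[mask & is_plus])
        minus_map[name] = np.sort(pos[mask & ~is_plus])

    tags = AlignedTags(
        chrom_sizes=dict(config.chrom_sizes),
        plus_positions=plus_map,
        minus_positions=minus_map,
        read_length=config.read_length,
    )
    tags.validate()

    if config.duplication_rate > 0:
        # derived seed keeps the whole library a function of config.seed
        tags = apply_pcr_duplication(
            tags, config.duplication_rate, seed=(config.seed + 1) % 2**31
        )

    name_arr = np.asarray(names, dtype=object)
    truth = {
        "sites": pd.DataFrame(
            {"chrom": name_arr[site_chrom], "position": site_pos}
        ),
        "sono_regions": pd.DataFrame(
            {
                "chrom": name_arr[sono_chrom],
                "start": sono_start,
                "end": sono_start + config.sono_region_width,
            }
        ),
        "reads": pd.DataFrame(
            {
                "chrom": name_arr[chrom_idx],
                "strand": np.where(is_plus, "+", "-"),
                "position": pos,
                "origin": np.asarray(["signal", "sono", "background"], dtype=object)[origin],
                "anchor": is_anchor,
            }
        ),
    }
    return tags, truth


def apply_pcr_duplication(
    tags: AlignedTags, duplication_rate: float, seed: int
) -> AlignedTags:
    """Duplicate each tag k extra times with k ~ Poisson(duplication_rate).

    Uses an inverse-CDF coupling (one uniform per tag, k = F^-1(u)), so at a
    fixed seed the number of duplicates is monotone non-decreasing in the
    rate: complexity decreases monotonically as the rate grows.
    """
    if duplication_rate < 0:
        raise ValidationError(f"duplication_rate must be >= 0, got {duplication_rate}")
    if duplication_rate == 0:
        return AlignedTags(
            chrom_sizes=dict(tags.chrom_sizes),
            plus_positions={c: v.copy() for c, v in tags.plus_positions.items()},
            minus_positions={c: v.copy() for c, v in tags.minus_positions.items()},
            read_length=tags.read_length,
        )
    rng = np.random.default_rng(seed)
    out_plus: dict[str, np.ndarray] = {}
    out_minus: dict[str, np.ndarray] = {}
    for strand_map, out in ((tags.plus_positions, out_plus), (tags.minus_positions, out_minus)):
        for chrom in sorted(strand_map):
            positions = strand_map[chrom]
            u = rng.random(len(positions))
            k = poisson.ppf(u, duplication_rate).astype(np.int64)
            out[chrom] = np.repeat(positions, 1 + k)  # repeat keeps sort order
    return AlignedTags(
        chrom_sizes=dict(tags.chrom_sizes),
        plus_positions=out_plus,
        minus_positions=out_minus,
        read_length=tags.read_length,
    )


def _kind_from_label(label: str) -> str:
    low = label.lower()
    if "igg" in low:
        return "igg"
    if "input" in low or "sono" in low:
        return "input"
    return "chip"


def simulate_cohort(
    specs: Sequence[tuple[str, SimulationConfig]],
    outdir: str | Path,
    write_truth: bool = False,
) -> pd.DataFrame:
    """Simulate a labelled cohort: one tagAlign file per library plus a
    metadata TSV (dataset_kind inferred from the label: ``igg``/``input``
    substrings mark controls).

    Returns the metadata table (library_id, paths, seeds).
    """
    if not specs:
        raise ValidationError("empty cohort specification")
    labels = [label for label, _ in specs]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValidationError(f"duplicate cohort labels: {dupes}")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metadata: list[LibraryMetadata] = []
    rows = []
    for label, config in specs:
        tags, truth = simulate_library(config)
        path = outdir / f"{label}.tagAlign"
        write_tagalign(tags, path)
        if write_truth:
            truth["reads"].to_csv(outdir / f"{label}.truth.tsv", sep="\t", index=False)
            truth["sites"].to_csv(outdir / f"{label}.sites.tsv", sep="\t", index=False)
        kind = _kind_from_label(label)
        metadata.append(
            LibraryMetadata(
                library_id=label,
                study_id="synthetic",
                target=label if kind == "chip" else kind,
                condition="synthetic",
                dataset_kind=kind,
            )
        )
        rows.append({"library_id": label, "path": str(path), "seed": config.seed})
    write_metadata(metadata, outdir / "metadata.tsv")
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return table
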