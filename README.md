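# strandqc

Strand cross-correlation quality control for ChIP-seq libraries.

A ChIP-seq experiment that truly enriched its target leaves a geometric
signature in the aligned reads: around each protein–DNA contact point,
plus-strand reads pile up one half fragment upstream and minus-strand reads
one half fragment downstream. `strandqc` quantifies this signature and turns
it into the standard enrichment metrics used to triage large collections of
transcription-factor ChIP-seq datasets — without calling a single peak. It
is aimed at anyone who needs to judge whether a library (their own, or one
pulled from a public repository) actually worked before building analyses
on top of it.

## The metrics

For a library of uniquely mapped reads reduced to strand-separated 5′-end
coordinates, the **strand cross-correlation profile** is the Pearson
correlation between the plus- and minus-strand per-base tag-count vectors
as the minus profile is shifted upstream by *d* bp, over a grid of shifts
(default 0, 2, …, 400). The profile of a successful point-source ChIP has a
peak at the mean fragment length; every library additionally carries an
artifactual "phantom" peak at the read length. With cc(frag), cc(phantom)
and cc(min) the smoothed profile values at the fragment peak, the phantom
peak and the profile minimum:

    NSC = cc(frag) / cc(min)
    RSC = (cc(frag) − cc(min)) / (cc(phantom) − cc(min))

RSC is discretized into an integer **QC tag**:

| RSC           | QC tag | reading                  |
|---------------|--------|--------------------------|
| [0, 0.25)     | −2     | no read clustering       |
| [0.25, 0.5)   | −1     | minimal clustering       |
| [0.5, 1.0)    | 0      | intermediate             |
| [1.0, 1.5)    | +1     | high clustering          |
| [1.5, ∞)      | +2     | very high clustering     |

Alongside, **apparent library complexity** is the fraction of reads at
distinct (chromosome, strand, 5′-coordinate) positions
(high ≥ 0.8, low ≤ 0.5), and sequencing depth is binned at 1/5/12/24
million uniquely mapped reads. Cohort tools encode the expectation rules
(controls and knockout-background experiments *should* score low), pick
best replicates per factor/condition, aggregate per-study score maxima, and
count summit-level overlap between two peak lists (shared iff summits lie
within 200 bp).

A bundled simulator generates aligned-tag libraries with the features these
metrics respond to — point-source binding sites, Sono-seq-like
open-chromatin enrichment in controls, a uniform background with a
read-stacking (phantom) component, and PCR duplication — so the whole
pipeline is testable end to end without any sequencing data.

## Worked example

```python
from strandqc import (SimulationConfig, simulate_library, analyze_tags,
                      assign_qc_tag, library_complexity)

chip_cfg = SimulationConfig(seed=1)                      # 40% signal reads
ctrl_cfg = SimulationConfig(signal_fraction=0.0, n_reads=200_000, seed=1)

for name, cfg in [("ChIP", chip_cfg), ("control", ctrl_cfg)]:
    tags, truth = simulate_library(cfg)
    profile = analyze_tags(tags)                         # shift grid 0:2:400
    stats = library_complexity(tags)
    print(f"{name}: fragment peak = {profile.fragment_peak_shift} bp, "
          f"phantom peak = {profile.phantom_peak_shift} bp, "
          f"RSC = {profile.rsc:.2f}, QC tag = {assign_qc_tag(profile.rsc):+d}, "
          f"complexity = {stats.complexity:.3f} ({stats.complexity_class})")
```

prints

```
ChIP: fragment peak = 198 bp, phantom peak = 36 bp, RSC = 33.73, QC tag = +2, complexity = 0.933 (high)
control: fragment peak = 262 bp, phantom peak = 36 bp, RSC = 0.26, QC tag = -1, complexity = 0.990 (high)
```

The simulated ChIP (200-bp mean fragments, 36-bp reads) recovers the
fragment length at the cross-correlation peak and scores in the top QC
class; the background-only control has no fragment-length peak rising above
noise — its "fragment peak" location is arbitrary — and scores low, exactly
the asymmetry the metric is built to detect.

The same workflow is available from the shell:

```sh
strandqc simulate --out chip.tagAlign --seed 1
strandqc qc chip.tagAlign --out-dir qc_out --plots
strandqc classify --qc qc_out/qc.tsv --metadata metadata.tsv --out-dir tables
strandqc overlap peaks_a.bed peaks_b.bed --window 200
```

`strandqc qc` accepts tagAlign/BED6 and BAM input and writes one TSV row
per library (reads, fragment-peak shift, NSC, RSC, QC tag, complexity and
depth classes, diagnostic flags) plus an optional cross-correlation plot.

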