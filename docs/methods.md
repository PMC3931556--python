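# Methods

## The cross-correlation model

A sequenced ChIP fragment of length *F* covering a binding point at *s*
yields, with equal probability, a plus-strand read whose 5′ end is near
*s − F/2* or a minus-strand read whose 5′ end is near *s + F/2*. Over many
fragments this produces mirrored tag clusters on the two strands separated
by roughly the mean fragment length. The strand cross-correlation profile
measures this: for each shift *d* on a grid, the Pearson correlation
between the plus-strand per-base tag-count vector and the minus-strand
vector displaced upstream by *d*, computed per chromosome over positions
[0, L − d) and combined across chromosomes as a weighted mean with weights
L − d (so short contigs cannot dominate). Counts, not binary occupancy, are
correlated. The default grid is 0:2:400 (201 shifts), suited to
short-read libraries with fragments below ~400 bp.

The engine never materializes per-base vectors: all Pearson sums (Σx, Σx²,
Σy, Σy², Σxy) are accumulated exactly from the sparse
(position, multiplicity) representation in integer arithmetic, so it
matches a dense textbook computation to floating-point round-off (the test
suite pins this at 1e−9 against an independent dense oracle) while running
in O(tags × shifts) time.

### Peaks, metrics, QC tag

The profile is smoothed with a truncated moving average (default bandwidth
3 grid points) before peak calling; bandwidth 1 disables smoothing. The
phantom peak is read at the grid point nearest the read length — it is an
alignment artifact present in essentially every library, arising where
mappable positions stack reads on both strands at a read-length offset.
The fragment peak is the argmax over grid points more than an exclusion
half-width (default 10 bp) from the read length; the baseline is the grid
minimum of the smoothed profile; ties break toward the larger shift. Then

    NSC = cc(frag) / cc(min)            (requires cc(min) > 0)
    RSC = (cc(frag) − cc(min)) / (cc(phantom) − cc(min))

Degenerate cases are flagged, never raised: a flat profile gives RSC 0 with
`degenerate_rsc`; a non-positive baseline gives NSC `nan` with
`degenerate_nsc` (this occurs routinely on synthetic background-only
libraries, whose profile minimum is slightly negative noise; real genomes
carry genome-wide coverage structure that keeps the minimum positive).

RSC maps to the integer QC tag through half-open intervals
[0, 0.25) → −2, [0.25, 0.5) → −1, [0.5, 1.0) → 0, [1.0, 1.5) → +1,
[1.5, ∞) → +2. The published interval endpoints overlap; assigning
boundaries rightward makes the top class exactly "RSC ≥ 1.5". Negative RSC
is clamped to 0 with a warning; non-finite RSC is an error.

Manual inspection of cross-correlation plots is operationalized as flags:
`phantom_dominant` (global smoothed maximum inside the exclusion window),
`multi_peaked` (more than one local maximum above baseline + 50% of the
fragment-peak prominence — e.g. periodic fragment-size distributions), and
`fragment_near_read_length` (fragment peak below 1.5× read length —
size-selection trouble). These mark profiles whose metrics should not be
taken at face value; they do not alter the metrics.

## Complexity and depth

Apparent library complexity = distinct (chromosome, strand, 5′-coordinate)
triples / total uniquely mapped reads. Strand-aware counting distinguishes
sense/antisense stacks at the same base. It is "apparent" because it
confounds PCR duplication with depth: even a perfect library saturates
under deep sequencing, so depth is always reported alongside and no
saturation-corrected estimator is attempted. Classes: high ≥ 0.8,
low ≤ 0.5, medium between (both printed edges inclusive). Depth bins are
left-closed at 1/5/12/24 million reads; the verbal classes follow the
stated rules strictly, so below 1 million is severely undersequenced and
only *more than* 12 million is deep — exactly 12,000,000 reads sits in the
12–24M bin but is classed moderate.

## Expectation rules and aggregation

Each library's metadata maps to an expected outcome in fixed rule order:
input/IgG controls → expected_low (control status dominates everything
else); knockout of the assayed factor → expected_low; knockdown of the
factor, unstimulated inducible factors, perturbations of other factors and
time courses → unknown (binding cannot be ruled in or out); everything
else → expected_high. expected_high is met by tags {+1, +2}, expected_low
by {−2, −1}. "Best replicate" per (study, target, condition) is the
maximal-RSC record — RSC is the quality axis everything else scores on —
with ties broken by read count then library id for determinism. The
condition string is treated as opaque; the package does not decide what
granularity (cell type, treatment, time point) a condition encodes.

## Summit overlap

Two peaks overlap iff their summits lie on the same chromosome within the
window (inclusive ≤, default 200 bp). Counting is per-peak from both sides
(a single peak may mark several on the other side), implemented as a
sorted sweep proven equivalent to the all-pairs scan in tests. Summits
come from 1-bp features, interval midpoints, or the narrowPeak offset
column (its −1 sentinel falls back to the midpoint with a warning).

## The simulator

The generator emulates the statistical structure the metrics respond to,
on a default single 10-Mbp chromosome with 36-bp reads:

- **Signal** (`signal_fraction`, default 0.4; `n_sites`, default 10,000):
  a site is chosen uniformly, a fragment length drawn from
  Normal(200, 20) truncated to [read_length, 2 × mean], the fragment
  centred on the site, and one end sequenced (fair coin): plus tag at the
  left end or minus tag at the right end. Infeasible draws near chromosome
  edges are redrawn with an iteration cap.
- **Sono-seq control enrichment** (`sono_fraction`, default 0;
  `sono_regions` 2,000 of width 600 bp): same fragment mechanics, but
  centred uniformly within a randomly chosen open-chromatin region. The
  clustering is broader than point-source signal yet still yields a
  fragment-length correlation peak — the mechanism by which real control
  libraries can score like successful ChIP.
- **Background** (remainder): uniform 5′ positions with a fair strand
  coin, except that a fraction (`anchor_fraction`, default 0.1) is drawn
  from a pool of `anchor_sites` (default 100,000) "mappability anchors"
  stacking plus reads at *a* and minus reads at *a* + read_length. This
  read-stacking component reproduces the phantom peak. It is not optional
  garnish: RSC is *defined* relative to the phantom peak, and a background
  with no phantom structure would make every noise maximum register as
  RSC ≥ 1. Defaults were set by magnitude calculation — at 2×10⁵ reads on
  10 Mbp they give a phantom correlation excess near 10⁻², an order of
  magnitude above the ~3×10⁻⁴ correlation noise, comparable to real
  mammalian input libraries.
- **PCR duplication** (`duplication_rate`, default 0): each tag gains
  k ~ Poisson(rate) extra copies. Sampling uses an inverse-CDF coupling
  (one uniform per tag, k = F⁻¹(u)), so at a fixed seed duplicate counts —
  and hence complexity loss — are monotone in the rate by construction,
  not merely in expectation.

Everything is a deterministic function of the config seed; the duplication
stage derives its seed from it. Per-read truth labels
(signal/sono/background, anchor membership) and site/region tables are
returned alongside the tags.

What the simulator does **not** model: sequence content, mappability maps,
GC bias, fragment-size selection distributions beyond the truncated
normal, enzymatic-digestion periodicity, broad histone-mark domains, or
copy-number structure. Passing tests therefore demonstrate that the
metrics respond correctly to read-clustering geometry, duplication and
control enrichment — not that they are robust to sequence-level artifacts
of real genomes. Broad marks (H3K9me3/H3K27me3-like) need different
metrics entirely and are out of scope.

## Numerical and design choices

- Grid/peak defaults: shift grid 0:2:400, smoothing bandwidth 3,
  phantom-exclusion half-width 10 bp — small values that stabilize the
  argmax on a 2-bp grid without displacing genuine peaks. Smoothing can
  move a knife-edge peak by one grid point; parameter-recovery tolerances
  (±20 bp) absorb this.
- Chromosomes with reads on a single strand, or zero-variance count
  windows, are skipped with a logged warning; a strand empty genome-wide
  is an error (the correlation does not exist).
- Test problem sizes follow the package's study conditions: strong-ChIP
  checks at 5×10⁵ reads / 10 Mbp / 10⁴ sites, background and control
  checks at 2×10⁵ reads, monotonicity sweeps as medians over 5 seeds, and
  a 20-seed background panel for the low-score guarantee.
- Survey-scale figures quoted in the literature for public-repository
  cohorts (score distributions over hundreds of libraries) require the
  original corpora; this package reproduces the rules and the qualitative
  phenomena, and its aggregation tables compute the same summaries for any
  user-supplied cohort.

## Known limitations

- Apparent complexity is depth-confounded by design; no PBC-style split
  metrics or library-size extrapolation.
- NSC is undefined (flagged) when the profile minimum is non-positive,
  which is typical for synthetic background-only libraries.
- The QC tag calibration targets genomes of roughly mammalian size and
  structure; very small or unusually structured genomes need different
  thresholds.
- The CLI reads whole libraries into memory; libraries of hundreds of
  millions of reads are better pre-filtered per chromosome.
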