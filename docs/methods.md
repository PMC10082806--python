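# Methods

## The problem

Two methylomes of the same individual — e.g. a tumour at diagnosis and at
relapse — are compared at every CpG group. The per-group methylation
frequency β is the fraction of methylated calls among analyzed calls, and
the object of interest is the difference track Δβ = β_test − β_control,
ordered along each chromosome. Differentially methylated regions (DMRs) are
maximal stretches where the underlying mean of Δβ departs from 0. The
difficulty specific to whole-genome long-read methylomes is that CpGs are
spaced very unevenly: dense islands of 10–30 bp spacing alternate with
sparse stretches of hundreds of bp, and a segmentation that ignores spacing
either shreds islands or glues unrelated sparse CpGs together.

## The model

Δβ_i is modelled as the sum of two independent processes,

    Δβ_i = m_i + ε_i,     ε_i ~ N(0, σ_ε²) truncated to [−1, 1],

where m_i is an unobserved piecewise-constant mean level. m_i persists for
geometrically distributed runs; when it changes it jumps by a Gaussian
increment δ ~ N(0, σ_μ²). The model is *heterogeneous*: the per-step jump
probability depends on the genomic distance d between consecutive CpG
groups,

    η(d) = θ/2 + (1/2 − θ)·exp[ log(θ) / (d / d_Norm) ],

which rises monotonically from θ/2 as d → 0 to (1 − θ)/2 as d → ∞ and
equals θ − θ² at d = d_Norm. Nearby CpGs (inside an island) therefore
rarely change level, while a level change across a long gap is cheap.
Emissions are truncated Gaussians because Δβ is bounded in [−1, 1]; the
truncation matters near the extremes (|m| close to 1, e.g. a fully switched
island), where an unbounded Gaussian would misprice the observations.

## Decoding

The continuous mean level is discretized to a symmetric grid of `n_states`
candidate levels on [−1, 1] (odd count, so 0 is always a state) and the
maximum a posteriori state path is found by the Viterbi algorithm:

* initial distribution ∝ N(level; 0, σ_μ²) on the grid;
* at step i, stay with probability 1 − η(d_i); jump to a different level k
  with probability η(d_i) times the increment density
  N(level_k − level_j; 0, σ_μ²), renormalized over k ≠ j;
* emission log-density: truncated Gaussian at the state's level with σ_ε.

All arithmetic is in log space; backtracking ties resolve to the lower
state index, making decoding deterministic. Runs of equal state are merged
into segments; a segment's reported mean Δβ is the unweighted empirical
mean over its member CpG groups (matching the emission model, which treats
every group equally regardless of coverage). Chromosomes are decoded
independently. Exactness of the implementation is verified against
exhaustive enumeration of all state paths on small instances.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| θ | 0.1 | baseline jump parameter; sets both η limits. |
| d_Norm | 1000 bp | distance scale of η; places the inflection above typical intra-island spacing so island-internal CpGs rarely break segments. |
| n_states | 41 | grid step 0.05 on [−1, 1], well below the 0.3 calling cutoff. |
| ω | 0.9 | variance ratio: σ_μ² = ω/(1−ω)·σ_ε², i.e. jumps ~3× the noise s.d. |
| min_called_sites | 5 per sample | β from fewer calls has ≥ ±0.2 granularity; such groups are dropped at the join. |
| Δβ cutoff | 0.3 | calling threshold on a segment's |mean Δβ|. |
| α | 0.05 | rank-sum significance threshold (raw p; optional Benjamini–Hochberg flag, off by default). |
| min_cpgs | 5 | the rank-sum test has essentially no power below n = 4 groups. |

σ_ε is estimated per chromosome from the lag-1 differences of Δβ: for a
piecewise-constant signal the differences are noise except at the rare
breakpoints, so the normalized median absolute deviation of the differences
divided by √2 is a jump-robust estimate of the noise s.d. (verified on
two-level tracks, where the naive s.d. overestimates by >2×). Constant
tracks are floored at σ_ε = 10⁻³ with a warning. θ and d_Norm are
configuration, not estimated.

## DMR calling and description

A segment is reported as a DMR when |mean Δβ| > cutoff, the two-sided
Wilcoxon rank-sum test of the member per-CpG-group β values (test vs
control) gives p < α, and it spans ≥ min_cpgs groups. The test uses the
exact null distribution up to combined n = 20 without ties, otherwise the
normal approximation with midranks, tie-corrected variance and continuity
correction; segments with < 2 groups are untestable (p = 1, warned). DMRs
are labelled hyper-/hypo-methylated by sign, and described by CpG density
(100 × CpG sites / bp) with resolution classes at ≤ 2 (WGBS limit), ≤ 3
(ERRBS limit) and > 3 CpG/100 bp, boundaries inclusive.

## Annotation

Genic elements are derived per transcript: 1to5Kb ([TSS−5000, TSS−1000)),
promoter ([TSS−1000, TSS)), first exon, internal exons, introns, and —
when CDS bounds are given — 5'/3' UTRs as exonic sequence outside the CDS;
all strand-aware and clipped at 0. Overlap is any-basepair (≥ 1 bp), DMRs
may carry multiple elements (no priority is imposed when a DMR spans, say,
promoter and first exon), and multi-transcript genes are deduplicated by
symbol. Region groups: Reg = {1to5Kb, promoter, 5'UTR, first exon},
GB = {internal exons, introns}; a DMR with no genic or enhancer overlap is
intergenic. CGI vs NoCGI is a separate context flag set by ≥ 1 bp island
overlap.

## Enrichment

For a feature class GF, the statistic is
log2[(Size_GF^DMR / Size_Total^DMR) / (Size_GF^Genome / Size_Total^Genome)]
— the DMR base-pair fraction in the feature over the feature's genomic
fraction. Zero overlap is reported as −∞ ("depleted below resolution").
Significance is Monte Carlo: each simulation re-places the same number of
segments with the same size multiset uniformly (chromosome ∝ length among
chromosomes long enough, start uniform within bounds, pooled genome-wide —
per-chromosome counts are not preserved), and the two-sided empirical
p-value is the add-one-corrected rank of the observed overlap's distance
from the simulation median, so p ≥ 1/(n_sims+1) and doubling n_sims halves
the floor. Ranking uses the overlap fraction rather than the log statistic:
the two order identically, but the overlap stays finite at zero, so a fully
depleted simulation cannot out-rank a strongly enriched observation. The
default n_sims = 10,000 is a desk-scale setting; genome-scale analyses
should raise it (the p floor scales accordingly). Placement is not
mappability- or gap-aware; an exclusion BED can be emulated by subtracting
regions from the chromosome sizes upstream.

## Methylation entropy

Over a window of b consecutive CpG sites (default b = 3), every read with
unambiguous calls (|LLR| > 2.5) at *all* b sites contributes one binary
pattern; the window's entropy is ME = (1/b)·Σ −(n_i/N)·log2(n_i/N), i.e.
per-site Shannon entropy of the pattern distribution: 0 when one pattern is
universal, 1 when all 2^b patterns are equifrequent. Windows with fewer
than min_reads (default 5) fully covering reads are skipped; a feature's
value is the unweighted mean over its sliding windows (step 1 CpG). ME is
invariant under a global swap of methylated/unmethylated labels.

## The synthetic-data generator

The generator emulates the structure the caller assumes, not raw signal:

* **CpG landscape** — alternating blocks: background stretches (mean 60
  groups at mean 150 bp spacing) and islands (mean 30 groups at 20 bp),
  giving ~1 CpG group per 100 bp overall, the density regime of whole-
  genome long-read methylomes; one CpG site per group.
* **baseline methylation** — bimodal: islands β = 0.1, background β = 0.9.
* **planted DMRs** — contiguous runs of CpG groups (default 8 regions of
  20 groups) shifted by ±effect in the test sample, clipped to [0, 1].
  By default direction follows context (islands gain, background loses
  methylation — the canonical cancer pattern), so clipping never silently
  erodes the planted effect; a random-direction mode exists.
* **counts** — coverage ~ Poisson (default 25×); methylated counts
  beta-binomial with precision 20 (overdispersion standing in for
  biological and caller noise), plain binomial as a switch.
* **reads** — when requested, reads span 10 consecutive groups and share a
  single read-level β draw, giving within-read pattern correlation; the
  emitted frequency table is then recomputed from the reads, so both views
  are consistent.

Everything is deterministic given the seed. What the generator does *not*
model: multi-CpG groups, strand effects, mappability gaps, copy-number or
purity shifts, LLR magnitude variation (synthetic calls are ±5), or
spatially correlated baseline drift. Passing benchmarks therefore
demonstrate correct recovery under the model's own assumptions plus
realistic counting noise — not robustness to alignment artefacts or
sample contamination.

## Benchmark scoring

CpG-level: every CpG group is labelled hyper/hypo/null by the truth and by
the calls; precision, recall and F1 are computed per direction and pooled
(a correct position with the wrong direction counts against both).
DMR-level: a called region is a true positive when it has ≥ 50% reciprocal
overlap with a same-direction truth region (threshold exposed).

The shipped problem sizes — two chromosomes of ~12 block pairs (~2,000
joined CpG groups) and 8 planted DMRs per replicate, 50 replicates for the
headline figure — were chosen so the whole benchmark runs in seconds while
every DMR still sits in an unambiguous local context; scores were stable
when the track length was doubled.

## Numerical and design notes

* The entropy formula is implemented in its canonical per-site Shannon
  form; the normalization constant is absorbed into the base-2 logarithm.
  This matches the stated extremes (0 for a universal pattern, 1 for
  equifrequent patterns), which a literal reading of some printed variants
  of the formula does not reproduce.
* Δβ is test − control throughout (relapse − diagnosis in the motivating
  comparison).
* The coverage-filter join drops CpG groups absent or under-covered in
  either sample; no imputation is attempted.
* η's θ is restricted to (0, 0.5): outside that interval the two limits of
  η(d) invert and the formula no longer defines a jump probability.
* Viterbi is O(n·K²) per chromosome with K = n_states; K = 41 decodes
  ~10⁵ CpG groups per second per chromosome on one core.

## Known limitations

Two-sample pairs only (no covariates, no multi-sample joint segmentation);
no posterior-marginal (forward–backward) decoding; no EM refinement of θ;
enrichment null is not GC- or distance-matched; entropy is not
haplotype-resolved.
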