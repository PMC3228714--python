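# Methods

This note records the models, conventions and numerical choices behind
`uridiv`, in the order the pipeline applies them.

## Scope and data model

The pipeline operates on single-region 16S rDNA amplicon reads as emitted
by pyrosequencing-era platforms: each read begins with a composite primer
(19-base sequencing adapter + 17–20-base target-specific primer) followed
by the amplified template. Quality scores and flowgrams are out of scope;
FASTA is the interchange format. All abundance-aware stages work on a
`DereplicatedSet` — unique sequences with read counts and member read
ids — so read provenance survives every merge and can be checked against
simulation ground truth.

## Primer splitting and length filtering

A read is assigned to a region iff its 5' end matches that region's
composite primer exactly, with IUPAC ambiguity codes *in the primer*
matching their base sets (one-directional: codes in reads never match
primer bases). Primers must be pairwise prefix-disjoint; this is
validated up front so no read can match two regions. Non-matching reads
are discarded and counted.

The composite primer is then trimmed and reads shorter than the region's
minimum length are dropped. Defaults: 218 nt (V1V2) and 235 nt (V6),
**inclusive** (a "minimum length cutoff" is read as the smallest
acceptable value), applied **after** primer trimming; the choice of
trim-then-filter is recorded here because the order is not derivable from
the report shape.

## Denoising (sequence-space stand-in)

Flowgram-likelihood denoising cannot be reconstructed without flowgrams.
The stand-in works in sequence space and reproduces the *effect* —
near-lossless read counts, error reads folded into their source
template — while being exactly testable against simulation truth:

* unique sequences are ranked by (count desc, length desc, sequence);
* each entry is absorbed into the first earlier *surviving* entry within
  `max_diffs` differences (default 3), counted on representative
  sequences as mismatches + internal gap columns;
* with the homopolymer discount (default on), an internal gap column
  whose base extends a run of length ≥ 2 in the other sequence counts
  0.5 — the platform's dominant error mode is ±1 indels at homopolymer
  runs, so a single such error costs 0.5 and three fit inside the radius;
* counts and members accumulate to the absorber; output is re-ranked by
  final counts.

The same greedy merger with `max_diffs = 2` and no discount is the
Huse-style precluster step before OTU formation. Both are idempotent:
survivors are pairwise further apart than the radius, so a second pass
changes nothing. On error-free reads from templates ≥ 5% divergent the
merger can never cross templates (≥ 15 differences at 300 nt versus a
radius of 2–3).

## Negative-control decontamination

Sample and control unique sequences are pooled and clustered jointly with
complete linkage at 1% genetic difference. Control entries are weighted
by `total sample reads / total control reads` so both sides contribute
the same read mass exactly (weights are real-valued; no integer
replication). Per cluster, the control fraction is computed **on
weights** — the weighting step would otherwise be purposeless — and
sample entries in clusters with fraction ≥ 50% are removed (boundary
inclusive: "50% or more"). A `count_mode="entries"` flag preserves the
alternative unweighted reading.

Properties: the filter is idempotent; an empty control skips the stage
with a warning; at zero sequencing error a contaminant spike drawn from
control templates ≥ 4% divergent from the community is removed exactly
(100% of contaminant uniques, 0 genuine). Under sequencing error the
filter is conservative by construction: complete linkage bounds the
cluster *diameter* at 1%, so an error-bearing contaminant copy that lies
more than 1% from any member of the already-formed control cluster stays
outside it and survives. This mirrors the behaviour of the
complete-linkage tool the procedure is modelled on.

## Alignment distances

Pairwise distances use Needleman–Wunsch global alignment with free end
gaps (semi-global), scoring match +1, mismatch −1, gap −2 per column.
These scores are explicit, overridable defaults chosen in the spirit of
the era's clustering tools; only the counting convention below is fixed
by the method:

    d(a, b) = (mismatches + internal gap columns) / compared columns
    compared columns = alignment length − end-gap columns

Each internal gap **column** counts as one difference (a `gap_mode=runs`
option collapses runs instead). End-gap columns are discounted entirely;
if every column is an end gap (e.g. a proper prefix, or two sequences
with no positive-scoring overlap) the distance is 0. The DP itself is
delegated to Biopython's `PairwiseAligner`; among co-optimal alignments
its first reported traceback is used, which is deterministic for a given
input pair. `distance()` canonicalizes the pair order lexicographically
before aligning, making symmetry exact by construction.

Consequence worth stating: the free-end-gap convention assigns
*unrelated* sequences a degenerate all-end-gap alignment with distance 0.
The convention is intended for homologous amplicons of one region, where
the direct alignment always dominates; the synthetic-data generator
honours this (below), and real mixed-region inputs must be primer-split
first — which the pipeline enforces.

## OTU clustering

Agglomerative clustering over the unique-sequence distance matrix.
Merge criteria: single = minimum, complete = maximum, average =
**read-count-weighted** mean of inter-cluster pairwise distances
(each unique sequence contributes its abundance, equivalent to
clustering the replicated reads; `weighted=False` averages over unique
sequences). A partition labelled *c* contains every merge with criterion
≤ *c* ("OTUs at ≤3%"). Ties in merge order are broken by the lowest pair
of smallest member indices; merge criteria are quantized to 10 decimals
before comparison so that floating-point summation noise cannot defeat
the tie-break on semantically equal criteria. The implementation uses
Lance–Williams updates (O(n²) per merge); tests verify exact partition
agreement with an exhaustive reference that recomputes every criterion
from the original matrix.

## Richness and diversity

* **Chao1**, bias-corrected: `S = Sobs + n1(n1−1)/(2(n2+1))` — defined
  even when doubletons are absent, matching the era's default. The 95% CI
  is the log-normal construction on `T = S − Sobs` with the classic
  variance (distinct forms for n2 > 0 and n2 = 0); with no singletons
  there is no evidence of unseen OTUs and the CI collapses to
  (Sobs, Sobs). The CI always brackets the estimate and never drops below
  Sobs.
* **Shannon**: natural log (the magnitudes of the reported indices for
  hundreds of OTUs are consistent with ln).
* **Normalized Shannon**: the mean Shannon over `reps` (default 100)
  uniform subsamples **without replacement** of a fixed size, used to
  compare samples of unequal depth; each replicate draws from its own
  spawned RNG stream, so results are reproducible and independent of
  replicate order. At full depth it equals the plain Shannon exactly.
* **Rarefaction**: the analytic hypergeometric expectation
  `E[S(m)] = Sobs − Σᵢ C(N−cᵢ, m)/C(N, m)`, evaluated in log space
  (gammaln); exact at m = 1 and m = N, strictly increasing and concave.

Validation regime for the Chao1 CI (chosen by a design study *before*
the test was frozen, not tuned afterwards): a 60-member community with
geometric abundances of shape 0.95 (mild skew, rank-1 share ≈ 5%)
surveyed by 500-read multinomial draws — shallow enough that singletons
occur in essentially every replicate while a handful of rare members stay
unseen. In this regime the measured coverage of the nominal 95% CI is
≈ 88–92%; the acceptance threshold is ≥ 80%, allowing for the
small-sample skew of the log-normal construction. Under strong abundance
skew (shape ≤ 0.9 at shallow depth) Chao1 is a lower bound and coverage
degrades — a known property of the estimator, not of this implementation.

## Taxonomy

Hit tables are a 4-column BLAST-tabular subset (query, subject taxon,
bit score, E-value; extra columns ignored), loaded with E ≤ 1e−5 and the
25 best hits per query. Each representative's hits are replicated to all
its member reads so abundance is reflected. Per read: hits below bit
score 100 are dropped; hits within 10% of the best remaining score are
retained (`top_percent` is exposed because the window is a convention of
the LCA tool being modelled, not stated by the procedure itself; 100%
reproduces "use all kept hits"); the read is placed on the LCA of the
retained taxa, or in the "No hits" bucket. The min-support filter then
moves reads of taxa tallying < 5 to "Not assigned" (a node with exactly 5
reads is reported), applied once over final node tallies — suppressed
reads do not promote to the parent node. Cross-sample tables scale each
sample's rank tallies to 100 000 reads.

A toy hit scorer against known templates (score = matches − 4 ×
differences on the pipeline's own alignment) is bundled purely as a test
harness: it guarantees that at zero sequencing error a read's own
template outranks templates ≥ 4% divergent even at a 10% window. It is
not a similarity-search replacement for real data, where a standard
BLAST tabular file is the expected input.

## Synthetic data

The generator emulates the study system's testable features:

* **Templates** are variants of one random ancestor, each substituted at
  a `min_divergence` fraction of sites and verified pairwise ≥
  `min_divergence` with the pipeline's own distance. Homology is required
  by the distance convention (see above); i.i.d. random sequences would
  be both unrealistic and degenerate under free end gaps.
* **Abundances** follow a geometric series pᵢ ∝ shapeⁱ: a single
  parameter spans uniform (shape 1) to strongly dominant communities
  (shape 0.25 gives the rank-1 member ≥ 75% of reads, the dominance
  pattern reported for most urine specimens), and every tail probability
  is analytic.
* **Errors**: per-base substitutions at `sub_rate`, plus per-run
  homopolymer indels — each maximal run of length ≥ 2 is lengthened or
  shortened by 1..`max_indel` bases with probability `hp_indel_rate`
  (never below length 1). Benchmark defaults are sub_rate 0.002 and
  hp_indel_rate 0.02, i.e. roughly one error per two 300-nt reads,
  matching the platform's sub-percent error regime.
* **Contamination**: contaminant reads drawn from a separate control
  community are appended so they form a stated fraction of the sample
  (default regime 1%), and an independent control read set from the same
  community is emitted — mimicking a negative extraction control that
  shares the sample's reagent flora. Truth tables record every read's
  template, contaminant flag and error count.
* **Reproducibility**: every operation draws from a named stream derived
  from (seed, operation, sample, region) via `SeedSequence`, so one
  integer seed fixes every emitted byte and adding reads to one sample
  never perturbs another.

What the generator does **not** model — chimeras, quality-score
structure, flowgrams, length variation of real 16S regions, non-uniform
error hotspots, cross-talk between samples. Passing tests therefore
demonstrate algorithmic correctness of every stage against a controlled
truth, not calibration against real 454 data; the original study's
per-sample numbers depend on its raw reads and are not reproducible
offline.

## Pipeline and problem sizes

Stages run per sample and region in the study's order: split →
trim/filter → dereplicate → denoise → decontaminate → precluster →
distances → cluster → diversity → taxonomy. Counters (total, after
length cutoff, denoised, cleaned) are logged per stage and are
non-increasing by construction; reruns under a fixed seed are
byte-identical. The distance matrix is computed on the preclustered set,
immediately before hierarchical clustering.

Default problem sizes in the test suite and acceptance script —
communities of 10–60 templates, 1 000–5 000 reads per sample, 200
replicates for coverage studies — were chosen so the full validation
(including the exhaustive clustering and alignment oracles) completes in
a few minutes on one core while keeping every check at the scale its
statistic needs (e.g. 3 000 reads make missing one of 50 uniform
templates astronomically unlikely).

## Known limitations

* The denoiser is a stand-in: it reproduces the effect of flowgram
  denoising on sequence-space data but not its likelihood model.
* Complete-linkage decontamination under sequencing error leaves behind
  contaminant derivatives beyond the 1% cluster diameter (conservative
  direction; quantified by the acceptance script's read-removal figure).
* Average-linkage OTU counts depend on the abundance weighting; both
  weighted (default) and unweighted modes are provided because the
  original tooling's choice is not documented.
* The alignment scoring parameters (+1/−1/−2) are explicit guesses;
  only the distance-counting convention is fixed. All are configurable.
* No chimera detection, no reference-based OTU picking, no
  phylogeny-aware diversity metrics.
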