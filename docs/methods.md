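# Methods

## Overview

`tadakit` analyses targeted DamID (TaDa) experiments. A transcription
factor fused to *E. coli* Dam methyltransferase deposits adenine
methylation at GATC motifs near its binding sites; sequencing the
methylation-specific digestion products yields reads whose positions mark
bound regions. Because methylation also tracks chromatin accessibility, a
Dam-only control is sequenced alongside, and the signal of interest is the
per-region log2 ratio of fusion over control. All signal in this package
is quantified on **GATC fragments** — the intervals between consecutive
GATC cut positions — which are the natural resolution limit of the assay.

## Coordinate conventions

All coordinates are 0-based, half-open internally. GFF/GTF input (1-based,
inclusive) is converted on I/O. Fragment boundaries sit at motif start + 2,
the DpnI blunt cut between GA and TC. Any consistent offset in [0, 4]
yields identical per-fragment read counts for reads longer than 4 bp, so
this choice affects fragment coordinates, never counts. GATC matching is
literal and case-insensitive; `N` never matches (conservative and
reproducible). Gene spans follow the largest-transcript convention: the
TSS/TES are the min start / max end over a gene's transcripts, in
transcription direction; exons of all transcripts are merged.

## Signal model

Each aligned read contributes one count to the fragment containing its
strand-adjusted 5' end (the position adjacent to the methylated GATC). The
reference DamID pipelines extend reads across fragments; the 5'-position
rule used here is simpler, conservative, and equivalent for reads shorter
than the median fragment — a deliberate, documented simplification.

For a TF track with counts t_i (library L_t) and a control track c_i
(library L_c):

    score_i = log2( (t_i/L_t + c) / (c_i/L_c + c) ) − m

with pseudocount c = 0.5 reads scaled by the mean library size (prevents
infinities on zero-count fragments) and centring offset m equal to the
mode of the score distribution over well-covered fragments
(t_i + c_i ≥ 10), estimated by Gaussian kernel density on a 1024-point
grid. Mode centring anchors the unbound background at zero even when a
substantial minority of fragments is bound; a median-centring fallback is
available (`center="median"`). With n TF and m control replicates, all
n×m pairwise tracks are computed and averaged per fragment.

Consequences worth knowing: the score is antisymmetric under swapping TF
and control; it is invariant under library rescaling up to the
pseudocount term (≈0.01 log2 units at typical depths); and normalizing an
already-centred track is a no-op to the mode-estimation tolerance.

## Peak calling

Candidate peaks are maximal runs of ≥ `min_fragments` (default 2)
consecutive, non-chromosome-end fragments with score ≥ a threshold;
thresholds are score quantiles (default 0.95, 0.99, 0.995, 0.999). Peak
score is the mean member score (length-robust; sum available), the summit
the best member fragment. A sub-threshold fragment splits runs
(`max_gap=0` by default).

FDR is estimated by permuting the per-fragment scores genome-wide —
preserving the exact score multiset and fragment-length structure — and
re-scanning. For an observed peak of score s at threshold T:

    FDR(s) = [(1 + #shuffled peaks at T with score ≥ s) / n_shuffles]
             / #observed peaks at T with score ≥ s

Numerical choices, fixed in `PeakCallConfig`:

* **Plus-one pseudo-exceedance.** Keeps estimates strictly positive at
  finite shuffle counts (100 by default) and dominates in the
  rare-exceedance regime, making the estimate insensitive to doubling the
  shuffle count.
* **q-value monotonization.** A peak reports the smallest FDR among
  rejection sets {score ≥ s} containing it, so FDR is non-increasing in
  score across the list. (A "conservative" running-max in the other
  direction was tried first and rejected: one noisy top-rank estimate
  could veto an entire peak list.)
* **Sparse-null guard.** A threshold whose pooled shuffles produce fewer
  than 10 null peaks is unassessable (FDR = 1): with almost no null
  exceedances the ratio estimator is dominated by the pseudo-count and
  would certify any singleton run.
* Candidates from different thresholds that overlap are resolved keeping
  the lowest-FDR one; the final list is position-sorted and monotonicity
  is re-enforced by raising (never lowering) FDRs.
* Final filter is strictly `fdr < threshold` (default 0.05).

The procedure assumes the signal occupies a small fraction of fragments:
genome-wide permutation scatters bound-fragment scores, and chance
adjacency of two such scores produces null runs. The expected number of
such runs scales as (bound fragments)² / (total fragments), so detection
degrades when bound fragments exceed roughly 2–3% of the genome — on real
genomes (hundreds of thousands of fragments, thousands of peak fragments)
this is comfortably satisfied, and the synthetic defaults reproduce that
regime. On a pure-noise track the expected fraction of runs with ≥ 1
false FDR < 0.05 peak is close to the nominal 5%.

## Peak-to-gene assignment

A peak is assigned to every gene, on either strand, whose window from
6 kb upstream of the TSS to 1 kb downstream of the TES (both inclusive)
contains the peak's center coordinate, floor((start+end)/2). Distances
are signed in transcription direction (negative = upstream). Location
relative to a gene uses the full peak span with precedence
TSS > TES > within-gene > up/downstream; within-gene peaks are refined to
exon-only/intron-only when every bp lies in exons/introns. A peak
covering a whole short gene is `overlapping_TSS` by precedence. Promoter
windows are 5 kb upstream to 500 bp downstream of the TSS, strand-aware,
clipped at chromosome bounds. Gene-set overlaps are tested against an
upper-tail hypergeometric null with a sampling pool of 20191 (annotated
coding genes in the annotation release the defaults mirror); Fisher's
exact test is available.

## Colocalization statistics

* **Monte-Carlo overlap.** Set A is shuffled by relocating each interval
  uniformly within its own chromosome, preserving length; overlaps among
  shuffled intervals are allowed (the simplest exactly-testable null).
  Both statistics — number of A intervals overlapping B, and total bp
  overlap — get p = (1 + exceedances)/(n_shuffles + 1), never zero. The
  bp statistic is nearly continuous and its null p-values are uniform;
  the count statistic is discrete and tie-handling makes its p-values
  conservative (valid, not exact).
* **Placement statistic.** For a query interval, the exact probability
  that a uniformly placed interval of the same length within the domain
  lies at least as close to the reference set as the query does, computed
  by interval arithmetic over allowed start windows (no sampling).
  Distance between half-open intervals is max(0, gap); bookended
  intervals have distance 0. The domain defaults to whole chromosomes;
  promoter-restricted analyses pass promoter windows as the domain.
* **Coassociation.** The proportion of query intervals with placement
  p < α (α = 0.05, the conventional level; configurable). The matrix over
  several peak sets is symmetrized by averaging the two directions and
  clustered with average linkage on 1 − value. Note α interacts with
  reference density: if a reference set covers more than ~5% of the
  domain (after inflation by query length), even overlapping queries
  cannot reach p < 0.05. Peak sets on genome-scale domains are far below
  this.

## Aggregation profiles

The signal is a piecewise-constant step function (per-fragment scores or
any bedGraph); bins integrate the step function exactly, weighted by bp,
so bin means are free of sampling error. Midpoint mode anchors feature
centers with real-coordinate flanks; stretch mode maps each gene body
linearly onto a 2 kb pseudo-length with real flanks upstream of the TSS
and downstream of the TES. Minus-strand features are flipped so the axis
runs in transcription direction. Defaults: 10 bp bins, 2 kb pseudo-length.
Profiles report per-bin means across features, z-scores (deviation from
the plotted-region mean in SDs of the bin means; defined as 0 when the
region is constant), and a 95% band (1.96 × SE across features).
Heatmaps cluster the per-feature bin matrix with average linkage;
constant matrices keep input order.

## Motif utilities

PWMs carry base probabilities per position; log-odds use a
pseudo-probability of 0.001 per cell against a uniform background
(overridable). Scanning covers both strands and reports sites at
log-odds ≥ threshold × the maximum achievable score; non-ACGT bases can
never be part of a site. K-mer enrichment is an explicitly simplified
surrogate for de novo motif discovery: canonical (reverse-complement
merged) k-mer counts are compared against dinucleotide-preserving
shuffles of the same sequences (Altschul–Erickson doublet shuffle),
yielding z = (obs − mean)/sd per k-mer; degenerate null SDs are flagged
rather than divided by. Inter-motif mode distance bins nearest-neighbor
distances between two site sets within shared peaks (50 bp bins, ties to
the smaller distance).

## Synthetic experiments

The generator emulates what TaDa hands the pipeline, with ground truth:

| parameter | default | meaning |
| --- | --- | --- |
| chromosomes | 6 × 1 Mb | scaled-down six-chromosome genome |
| bases | i.i.d. uniform | GATC spacing geometric, mean 256 bp |
| genes | 60, spacing ≥ 8 kb | 2–5 exons, random strands |
| motif | CACGTG (E-box) | planted ≤ 2 kb upstream of the TSS |
| fraction bound | 0.3 | 18 bound genes |
| enrichment e | 8 | at fragments within 500 bp of a site |
| halo | 500 bp | Dam's local action range, fragment-binarized |
| accessibility | lognormal σ = 0.4 | shared across all samples |
| depth | 500k reads/sample | ~21 reads per fragment |
| dispersion | NB size 10 | ~4× Poisson variance at μ = 30 |
| replicates | 2 × 2 | TF and control |

Fragment i has methylation propensity a_i · b · len_i, multiplied by e
for TF samples when the fragment lies within the halo of a planted site;
counts are negative binomial around depth-scaled propensities; reads fall
uniformly within their fragment with random strand (so counting the
placed reads reproduces the drawn counts exactly — tested). The
accessibility factor a_i is the confounder the Dam-only control removes:
it cancels in the log-ratio (regression slope of background score on
log a_i is ≈ 0).

What the generator does **not** emulate: real base composition and GATC
clustering, chromatin-domain-scale correlated accessibility, PCR
amplification bias, mappability, or partial tissue specificity of the
driver. Passing recovery tests therefore demonstrate the pipeline's
statistical machinery, not robustness to those artefacts.

Recovery is scored against each site's enriched-fragment span (site ±
halo, i.e. exactly where excess signal was placed), pooled over five
independent experiments so the recovery rate is measured on 90 sites
rather than at single-experiment ±1-site granularity. Bound fragments
occupy ~0.4% of all fragments under the defaults, mirroring real peak
sets (thousands of peak fragments over hundreds of thousands of
fragments); this sparsity is what keeps the permutation null's
chance-adjacency rate low. A site whose halo
covers a single fragment (the site centred in a fragment longer than
1 kb, ~2% of placements at 256 bp spacing) is undetectable at
`min_fragments=2` by construction; this mirrors the real assay's
dependence on local GATC density and bounds attainable recall at ≈ 0.98.

## Problem sizes and determinism

Null calibration runs use a scaled configuration (2 × 200 kb, depth
100k, e = 1) so that 200 full repetitions remain a routine desk-scale
computation; recovery runs use the full default configuration. All
randomness flows from one root seed through named substreams
(`peaks.shuffle`, `sim.reads.<condition>.<rep>`, `coloc.shuffle`, …), so
identical seeds give byte-identical outputs, which the test suite
asserts at the file level.

## Known limitations

* Read-to-fragment assignment by 5' position undercounts fragments
  shorter than the read length relative to the extension rule.
* Permutation FDR assumes exchangeable background scores; strong
  position-dependent variance structure (e.g. copy-number variation)
  would violate it. A within-chromosome shuffle mode is provided.
* The placement statistic conditions on the reference set and query
  lengths; it is not a two-sided association test.
* K-mer enrichment does not replace PWM-based de novo discovery; it
  ranks exact words only.
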