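# Methods

`dhs-atlas` re-implements, as a tested library, the analysis chain used in
genome-wide DNase I hypersensitivity studies of complex tissues: detection
of accessible-chromatin hotspots and peaks from cleavage-tag data, assembly
of a cross-sample DHS master list, temporal clustering of accessibility,
interval-rule annotation (promoters, ChIP occupancy, region specificity),
per-cluster transcription-factor motif enrichment, and cross-species
conservation categories. This note records the models, the parameters that
matter, and the design choices made where the procedure was genuinely open.

## Hotspot model

Tags are 5′ cleavage positions on a reference genome. Per chromosome, tags
are summed within 150-bp windows advanced in 20-bp steps; a tag at position
p belongs to window [s, s+150) iff s ≤ p < s+150 (strand ignored). Note
that with a 20-bp start grid an interior tag is covered by 7 or 8 windows
depending on its phase modulo the step (150/20 is not an integer); the
windowed counts are used only relatively, so the phase wobble is
immaterial downstream.

Each window is scored against a binomial local background: with `t` tags in
the 50-kb region centered on the window (clipped at chromosome ends) and
`c` tags in the window, the score is the upper tail P(X ≥ c) for
X ~ Binomial(t, 150/50000), computed with `scipy.stats.binom.sf` (accurate
to far better than the 1e-3 relative error budget on the tested grid; the
test oracle is an arbitrary-precision tail sum). The 50-kb background
length is the conventional local-background scale for this model and is
configurable.

Windows with p ≤ threshold are merged into **hotspots** when their spans
overlap or abut within one step (20 bp); hotspot significance is the
minimum window p inside. Hotspots are internally scanned for local maxima
of the window counts (leftmost window of a plateau); 150-bp **peaks** are
emitted greedily from the highest maximum, skipping maxima whose peak would
overlap an already-emitted peak; every hotspot yields at least one peak.

**FDR calibration.** The detection threshold is not fixed: uniform random
tag sets at equal depth over the mappable genome are scanned with the
identical window → p-value → merge chain, and the FDR estimate at a
threshold is (mean simulated hotspot count) / (observed hotspot count).
The calibration is a bisection over −log10 p in [2, 12] (25 iterations)
for the loosest threshold with estimated FDR below the 1% target; window
p-values for the observed and null sets are computed once, so each
iteration only re-thresholds and re-merges. The default uses a handful of
null replicates inside the pipeline and 20 in the acceptance computation.
Library quality is the **SPOT score**: the fraction of tags falling inside
called hotspots.

At the full-scale depth of 25 million reads, samples are first
down-sampled by random sampling without replacement
(`downsample_tags`); demo-scale runs use 1 M tags directly.

## Master list and density matrix

Per-sample peak sets are merged across samples: transitively overlapping
peaks become one master DHS whose interval is the union span (abutting but
non-overlapping peaks stay separate); construction is idempotent and
provenance (contributing samples) is recorded. The raw accessibility of a
master DHS in a sample is the maximum tags-per-million window density over
windows intersecting it.

Normalization is three fixed steps in order: divide by the sample's SPOT
score (library-quality correction), transform by log10(density + 1), and
scale each row so its maximum is exactly 10 (all-zero rows stay zero; the
implementation divides by the row maximum before multiplying by 10 so the
maximum is exact in floating point).

## Temporal clustering

Rows of the normalized matrix are grouped by k-means (k = 12 by default;
Euclidean distance, k-means++ seeding, best of 25 initializations,
max 300 iterations, tol 1e-6, fixed seed — backed by scikit-learn).
Centroids over the ordered stages are labeled:

- **C** (constitutive) if (max − min)/max ≤ 0.2,
- **O** (other) if the profile has an interior minimum below both ends
  (valley shape),
- otherwise **E**/**M**/**L** by the argmax stage.

The flatness tolerance and the valley rule are package choices; published
figures show the labels but not a rule. All-zero rows are labeled C rather
than dropped, keeping the matrix aligned with the master list.

## Annotation rules

- **Promoter**: a DHS intersecting the strand-aware 1-kb upstream window of
  any TSS ([tss−1000, tss) on '+', [tss+1, tss+1001) on '−'). The strand
  handling is a package choice; "1 kb upstream" alone does not fix it.
- **Genomic partition**: precedence promoter ≻ exon ≻ intron ≻ intergenic;
  intergenic DHSs are split at 2.5 kb from the nearest TSS into
  proximal/distal (the boundary is a package choice).
- **ChIP occupancy**: a ChIP peak overlapping exactly one master DHS by
  ≥ 75 bp marks it occupied; peaks overlapping more than one DHS that
  deeply are excluded and tallied; peaks qualifying for none are tallied
  as non-overlapping.
- **Region specificity**: a target DHS is specific when it overlaps every
  DHS of every comparison set by < 25 bp (the cross-study mapping
  threshold); "present in a region" elsewhere means ≥ 1 bp overlap.
- **Pairwise overlap matrix**: entry (A, B) is the fraction of A's peaks
  overlapping any peak of B by ≥ 1 bp (asymmetric); clustering uses
  average linkage on 1 − (arithmetic mean of the two directions).

## Motif enrichment

A DHS carries a TF's motif when any hit of any motif model linked to that
TF, with scanner match p < 1e-4, overlaps the DHS by ≥ 1 bp (models pooled
by union; the threshold is read as 1e-4, the conventional scanner default,
though the source notation "10e-4" is ambiguous — both are configurable).
Enrichment of a TF in a cluster of n DHSs against a background of N master
DHSs (K carrying the motif, k in the cluster) is the inclusive upper tail
P(X ≥ k), X ~ Hypergeometric(N, K, n), via `scipy.stats.hypergeom.sf`
(log-gamma based, exact summation in effect). Bonferroni correction is
applied over the family of all TF × cluster tests in one run; significance
is reported at corrected p < 0.01.

## Conservation

Through an orthology interval map (source interval → at most one target
interval; split mappings collapsed to the largest-overlap block), each DHS
is **unalignable** (no mapping), **shared** (target overlaps a
partner-species DHS by ≥ 25 bp), or **diverged** otherwise. Region
distributions over the three categories are compared pairwise by Pearson
chi-squared on the 2 × 3 count tables without continuity correction
(df = 2; categories empty in both rows are dropped; low expected counts
produce a warning, not an error).

## Synthetic data: what it emulates and what it does not

The generator plants non-overlapping DHS intervals (default 2,000 of
200 bp on a 2 × 5 Mb genome, ≥ 300 bp apart) with archetype labels mixed
30/25/25/20% early/mid/late/constitutive. Tags are drawn multinomially
over genome segments: background rate 1 per bp, in-DHS rate =
enrichment_fold (default 10) × archetype weight at the stage, with weight
vectors E = (1, 0.4, 0.15), M = (0.3, 1, 0.3), L = (0.15, 0.4, 1),
C = (1, 1, 1) over stages (P0, P7, Adult) — qualitative temporal shapes;
no published per-cluster effect sizes exist, so these are package
defaults chosen once. Depth defaults to 1 M tags per sample so a full
demo run takes minutes on one CPU; the 25 M-read scale is a configuration
change.

ChIP peak sets place round(overlap_fraction × n_peaks) peaks inside
distinct true DHSs (guaranteeing ≥ 75 bp overlap) and the rest strictly
outside all DHSs. Motif hit tables are Bernoulli per TF × DHS with
probability background_rate outside the target archetype and
min(1, background_rate × odds) inside. Orthology categories are assigned
in exact largest-remainder proportions, with identity-length target
intervals on a partner genome.

The generator is intervals-only: no sequence composition, no DNase
cleavage sequence bias, no mappability gaps, no replicate structure, no
chromatin-domain autocorrelation. Passing tests therefore demonstrate the
correctness of the statistical machinery and interval rules under the
stated model, not robustness to the biases of real DNase-seq libraries
(the simulated-null FDR, in particular, shares the uniform-background
assumption with the generator, which is also the null the original
procedure states).

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open (BED) everywhere; FIMO-style input is
  converted from 1-based inclusive on read.
- p-values are floored at 1e-300 before −log10 transforms.
- Target-count rounding (e.g. overlap_fraction × n_peaks) uses Python's
  round-half-to-even; category counts use the largest-remainder rule.
- Zero observed hotspots make the FDR estimate 1.0 with a warning; empty
  tag sets yield empty tracks; empty regions/sets are dropped with
  warnings, never silently.
- k-means empty clusters are handled by scikit-learn's relocation rule;
  ties in peak ranking break toward the leftmost window.

## Problem sizes used in the shipped checks

Unit tests run on 1 × 200 kb genomes with 40 planted DHSs and 50 k tags.
The end-to-end checks use the demo scale above (2 × 5 Mb, 2,000 DHSs,
1 M tags, 20 null calibration replicates), 5,000-row clustering-recovery
matrices over 10 seeds, ≥ 1,000 null enrichment tests, and 200
chi-squared type-I replicates at n = 5,000 — sizes chosen so the whole
suite completes in minutes on a single CPU while keeping Monte-Carlo
error well below the asserted margins.

## Known limitations

- The hotspot caller implements the binomial-tail variant described for
  the published analysis, not a byte-compatible clone of the external
  Hotspot program (whose z-score and two-pass refinement are specified
  only in external material).
- The local-background total is computed from exact tag positions when
  available and estimated from overlapping window counts otherwise.
- Master DHS intervals are union spans of merged peaks by default; a
  centroid-150-bp representative is available via
  `build_master_list(..., representative="centroid150")`, but union is the
  primary tested path.
- The pairwise overlap matrix treats internally-merged comparison sets;
  heavily self-overlapping input peak sets should be merged first.
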