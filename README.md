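# dhs-atlas

Analysis toolkit for genome-wide DNase I hypersensitivity (DNase-seq)
studies of complex tissues — written for computational biologists who want
the full chain from aligned cleavage tags to a catalogued, annotated,
temporally clustered atlas of DNase I-hypersensitive sites (DHSs), with a
synthetic-data generator that makes every stage testable against known
ground truth.

## What it computes

**Hotspot detection.** Cleavage tags are summed in 150-bp windows at 20-bp
steps. A window with count *c* against *t* tags in the surrounding 50-kb
local background is scored by the binomial upper tail

P(X ≥ c),  X ~ Binomial(t, 150/50 000).

Significant windows are merged into *hotspots*; local maxima inside each
hotspot become fixed 150-bp *peaks*. The significance threshold is
calibrated against simulated datasets of uniform random tags at equal
sequencing depth so that the estimated false discovery rate
(simulated hotspots / observed hotspots) stays below 1%. Library quality
is the SPOT score — the fraction of tags inside hotspots. Full-scale
libraries are first down-sampled to 25 M reads without replacement.

**Master list & temporal clustering.** Per-sample peaks merge into a
non-redundant, non-overlapping master list. Each DHS's per-stage maximum
tags-per-million density is divided by the sample's SPOT score,
transformed by log10(density + 1), and row-normalized to a maximum of 10,
then partitioned by k-means (k = 12) into temporal groups labeled
E/M/L/O/C (early / mid / late / other / constitutive).

**Annotation & enrichment.** Strand-aware 1-kb-upstream promoter
assignment; genomic partition with promoter ≻ exon ≻ intron ≻ intergenic
precedence; ChIP occupancy under the ≥ 75 bp overlap rule (peaks
straddling two DHSs are excluded); region-specific sets by subtraction;
per-cluster TF motif enrichment by the cumulative hypergeometric
P(X ≥ k), X ~ Hypergeometric(N, K, n), Bonferroni-corrected.

**Conservation.** Via an orthology interval map, each DHS is *shared*
(orthologous region is a DHS in the partner species), *diverged*
(orthologous sequence, no partner DHS), or *unalignable*; region
distributions are compared by pairwise Pearson chi-squared.

## Worked example

Run the bundled synthetic demo (one 600-kb chromosome, 120 planted DHSs
with early/mid/late/constitutive temporal archetypes, 120 k tags per
stage):

```python
from dhs_atlas import pipeline

cfg = pipeline.RunConfig(n_chroms=1, chrom_length=600_000, n_true_dhs=120,
                         target_depth=120_000, n_null_replicates=2,
                         seed=17, chip_n_peaks=40)
report = pipeline.run_all(cfg, "demo_out")
```

The report (also written to `demo_out/report.json`) contains, among
others:

```
"P0":    {"spot": 0.2091, "n_hotspots": 89,  "fdr_estimate": 0.0056}
"P7":    {"spot": 0.2467, "n_hotspots": 121, "fdr_estimate": 0.0083}
"Adult": {"spot": 0.1915, "n_hotspots": 80,  "fdr_estimate": 0.0063}
"master_size": 121
"occupancy": {"total_peaks": 40, "occupying_peaks": 32,
              "non_overlapping": 8, "multi_overlap_excluded": 0}
"conservation": {"shared": 72, "diverged": 36, "unalignable": 12}
```

Each stage calls ~80–120 hotspots with a simulated-null FDR estimate
below the 1% target; roughly a fifth to a quarter of the tags fall inside
hotspots (the SPOT score); the 121 master DHSs split into 12 temporal
clusters; 32 of 40 simulated ChIP peaks occupy a DHS by ≥ 75 bp (the
planted fraction was 0.8); the conservation categories recover the
planted 60/30/10% split exactly. Comparing against the generator's truth:

```python
pipeline.validate_against_truth(report, report["_truth"])
# {'master_fdr': 0.0083, 'dhs_sensitivity': 1.0, 'cluster_purity': 1.0,
#  'enrichment_recovered': {'TF_early': True, 'TF_late': True},
#  'conservation_match_rate': 1.0}
```

A CLI mirrors the library (`dhs-atlas simulate | callpeaks | masterlist |
cluster | conserve | run-all`); see `dhs-atlas --help`.

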