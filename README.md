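# methylout

Rare hypermethylation-outlier (epivariant) analysis for haplotype-resolved
per-CpG methylation cohorts.

Long-read 5-base genome sequencing yields, for every sample, per-CpG read
coverage and methylation fractions in three *phasing modes* — all reads
(`combined`) and reads assigned to each haplotype (`hap1`, `hap2`) —
alongside phased small variants and SVs.  `methylout` screens such a cohort
for rare hypermethylation events, which are frequently allele-specific,
sit in otherwise hypomethylated regulatory elements, and can silence a
disease allele that ordinary variant interpretation misses.

## Method

For each CpG the cohort's combined-mode fractions define a reference
distribution (mean, sample SD, empirical Q95/Q5).  For a sample *s*, CpG
*c* and phasing mode *m* with depth ≥ 10×:

- z(s,c,m) = (x − mean_c) / sd_c,
- *c* is **hyper** when x > Q95_c + 3·sd_c, **hypo** when x < Q5_c − 3·sd_c.

CpGs are grouped into fixed 200 bp autosomal tiles; a tile is a candidate
for (s,m) when it holds ≥ 2 hyper CpGs and no hypo CpG, with mean z taken
over all covered tile CpGs.  Candidates pooled over the cohort are kept by
two rarity paths:

- **Path A** — the tile is carried by ≤ 2 unrelated families (any mode);
  carriers with mean z > 2 are reported.
- **Path B** — 3+ families carry the tile (a dynamic region); at most 2
  unrelated carriers with mean z > 5 are kept, and only if the lowest kept
  carrier exceeds the best dropped one by ≥ 3 z-units.

Each call is then annotated: allele-specific vs biallelic (candidate on one
haplotype with the other covered ≥ 10× and quiet, or on both); regular vs
large (runs of ≥ 3 adjacent called tiles); nearest rare variant (SNV
MAF < 0.5%, SV MAF < 1%) with a percentile rank of the carrier's
tile-variant distance against the same query in all other samples, an
empirical q curve over distance (q < 0.1 threshold), and a cis/trans label
from phased genotypes tested with a two-sided exact binomial; familial
sharing against a label-permutation null; DNase-hypersensitivity-site
enrichment against background tiles (present in ≥ 5 samples, |tile z| ≤ 1)
with two-sided Fisher tests; nearest-TSS/disease-gene annotation (±1 kb
promoter flag); and allelic expression imbalance at heterozygous SNVs
(minor allele fraction < 0.45 at ≥ 10 informative reads).

Because the real patient data of this kind sit under restricted access, the
package ships a first-class synthetic-cohort generator
(`methylout.synthetic_cohort`) with beta-binomial methylation, planted
allele-specific events, cis variants, trio families and ground-truth
manifests, so the whole cascade is testable end to end.

## Worked example

```sh
methylout simulate --out ex_bundle --seed 11 --n-samples 20 --n-cpgs 6000 \
    --n-events 6 --heritable-fraction 0.5
methylout run-all --bundle ex_bundle --out ex_run --seed 11 --n-perm 200
```

The run directory then contains `outlier_calls.tsv`:

```text
chrom  tile_start  tile_end sample_id phasing_mode  n_hyper  n_hypo   mean_z rarity_path allele_specificity  extent
 chr1        7000      7200      S006         hap2        2       0 2.363179           A    allele_specific regular
 chr1        9800     10000      S003         hap1        4       0 5.726296           A    allele_specific regular
 chr1       10000     10200      S003         hap1        2       0 5.418229           A    allele_specific regular
 chr1       17000     17200      S020         hap1        2       0 2.930879           A    allele_specific regular
```

30 calls over 29 unique tiles: S003's planted hap1 event spans two adjacent
tiles with mean z ≈ 5.4–5.7, confined to one haplotype, and every call here
is allele-specific — the hallmark the screen is built around.
`summary.json` reports the cohort statistics computed on this run:

```json
"sharing": {"n_calls_with_relative": 19, "n_shared": 2, "fold": 4.0, "p_perm": 0.254}
"q_distance_threshold": 732.1
```

i.e. calls in trio members were shared by a relative 4× more often than
under permuted family labels (not significant at this toy size), and tiles
are linked to rare variants at distances below ~732 bp (the planted cis
SNVs sit 500 bp away).  `expression_summary.tsv` shows 4/4 carrier
transcripts versus 10/76 (13%) control transcripts beyond the 45:55
allelic ratio, and `dhs_enrichment.tsv` a 1.43-fold regulatory-element
enrichment of outlier tiles over background (p = 0.013).

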