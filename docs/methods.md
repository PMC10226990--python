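# Methods

## Outlier model

The screen treats each CpG's cohort distribution of combined-mode
methylation fractions as the reference.  Per CpG we compute the mean,
sample SD (denominator n−1) and the empirical 5th/95th quantiles using
linear interpolation between order statistics (the "type 7" rule).  Neither
the quantile estimator nor the SD denominator is forced by the method
itself; both are package decisions, used consistently by the test oracles
and recorded here.

Haplotype-mode (hap1/hap2) methylation rates are z-scored against the same
combined-mode reference rather than per-haplotype references.  A fully
methylated single allele at a CpG whose population total methylation is
~10% sits many SDs above the reference, which is exactly what makes
mono-allelic events detectable; per-haplotype references would halve the
cohort depth and blur the signal.  The reference includes every sequenced
sample (probands and relatives); an exclusion list is accepted for
sensitivity analyses.

Flag thresholds use strict inequalities: hyper means fraction strictly
above Q95 + 3·SD, hypo strictly below Q5 − 3·SD.  A value landing exactly
on the boundary is normal.  Records at CpGs with SD = 0 or missing
reference rows are excluded and counted, never z-scored.

## Tiling and rarity

Tiles are the fixed grid [200k, 200(k+1)) in 0-based reference
coordinates, autosomes only; a fixed grid is the only reproducible reading
of "200 bp tiles".  A candidate needs ≥ 2 hyper CpGs and zero hypo CpGs;
its mean z averages **all** covered CpGs in the tile, not only flagged
ones, so one extreme CpG cannot carry a tile by itself.

Carrier counting is family-based: all calls within one family, and all
phasing modes of one sample, count once toward the rarity cutoffs.  Path B
ranks one representative per family (its best mean z) in descending order,
keeps at most two representatives with mean z > 5, and requires the lowest
kept value to exceed the highest dropped value by ≥ 3 z-units; if the check
fails the kept set shrinks by one and is re-tested, down to the empty set.
The two paths partition tiles by family count, so no tile can be reported
under both.

"Regular" vs "large" extent is assigned per maximal run of adjacent called
tiles (per sample, mode and chromosome): runs of ≤ 2 tiles are regular,
≥ 3 large.  The source wording overlaps at exactly two tiles; this package
assigns 2 → regular and exposes `two_tiles_large=True` to flip the
boundary.

Allele-specificity requires an informative negative: a call is
allele-specific only when the tile is a candidate on exactly one haplotype
*and* the other haplotype has ≥ 2 tile CpGs at ≥ 10× without being a
candidate.  Under-covered opposite haplotypes give "undetermined", never a
silent allele-specific label.

## Variant linkage

Distances are measured from the nearest tile edge to the nearest variant
breakend (0 when overlapping); rarity filters are MAF < 0.5% for SNVs and
< 1% for SVs, taken from a MAF annotation on the variant records (no
external database is queried).  The carrier's distance is ranked against
the identical query for the same tile in every other sample with the
add-one convention rank = (1 + #{others ≤ d}) / (1 + #others), so ranks
are never zero and ties count against the carrier.

The empirical q per distance bin is the mean percentile rank of links in
the bin, over log-spaced bins from 10² to 10⁶ bp (plus a [0, 100) bin).
The reported distance threshold is the largest bin midpoint with q < 0.1
among bins holding ≥ 5 links; a mean over one or two ranks is noise and a
single lucky far-distance link must not set the threshold.  The curve
itself reports every bin, plus a pool-adjacent-violators isotonic column
for plotting (q should not decrease with distance).  Bin scheme,
aggregation and the 5-link floor are package choices; all are arguments.

Cis/trans: a haplotype-resolved call paired with a phased variant is cis
when haplotypes match, trans otherwise; unphased variants (or combined-mode
calls) are routed to a manual-curation label.  The cis excess test is the
exact binomial at p₀ = 0.5, two-sided by doubling the smaller tail and
capping at 1; tests verify it against explicit pmf enumeration.

## Familial sharing and enrichment

An observation is one (sample, tile) call, any phasing mode, in a sample
whose family has ≥ 2 enrolled members; it is shared when any relative
carries a call at the same tile.  The null permutes family labels among
the call-carrying samples with relatives, holding call sets fixed;
fold = observed / mean(permuted) and p = (1 + #{perm ≥ obs}) / (1 + n_perm).
The summary reports the null's own mean, min and max.

Background tiles for regulatory-element enrichment require ≥ 5 samples
with ≥ 2 z-scored CpGs in the tile (the same coverage basis as calling)
and a tile-level mean z within ±1 (±2 as the looser published variant);
50,000 are drawn uniformly without replacement, seeded.  Overlap is any-bp
intersection with the component-labelled element BED; per component and
overall, fold is the ratio of overlap fractions and p a two-sided Fisher
exact test.

Annotation reports the signed distance to the nearest TSS (negative =
upstream of the tile), the nearest disease gene, and a promoter flag when
the tile intersects the closed window TSS ± 1 kb.

## Allelic expression

A count record at a heterozygous SNV is informative at ≥ 10 total reads
(strictly-greater variant of the floor is a flag); the minor-allele
fraction min(n₁,n₂)/(n₁+n₂) deviates when strictly below 0.45.  Carriers
(probands with the linked tile) and controls (probands without it) are
summarized as deviating/informative with integer percentages.

## Synthetic cohorts

The generator emulates the *statistical* structure of a haplotype-resolved
methylation cohort, not its molecular provenance:

- true rate per CpG, sample and haplotype ~ Beta(α, β); defaults
  α = 1.5, β = 13.5 (mean 0.1, SD 0.075), mimicking the hypomethylated
  regulatory loci where hypermethylation outliers are visible;
- coverage per CpG and haplotype ~ Poisson(20); observed fraction =
  Binomial(coverage, rate)/coverage; combined mode sums haplotype reads;
- CpGs at uniform positions with ≥ 2 bp spacing, 1 per 50 bp (≈ 4 CpGs per
  200 bp tile) over a 1 Mb default genome;
- planted events add `effect_delta` (default 0.5) to the true rate on the
  stated haplotype(s) over a 400 bp interval, clipped at 1; heritable
  events are copied to one seeded parent; families are trios;
- planted cis SNVs sit 500 bp from their event; background rare variants
  are uniform at 1 per 50 kb per sample — genome-wide rare-variant spacing
  — which is what gives planted cis variants their low percentile ranks;
- regulatory elements are random intervals with 16-component labels, with
  planted events covered by an element 90% of the time; the first few
  planted events are anchored on a TSS so allelic-expression validation has
  promoter-linked ground truth;
- allelic expression draws 200 FLNC reads per informative transcript,
  minor fraction 0.1 for carriers and 0.5 for controls.  At depths of a
  few dozen reads, binomial noise alone crosses the 45:55 bound often;
  200 reads puts control deviation near the ~15% level real cohorts show.

One seed determines everything; identical configs produce byte-identical
bundles.

What the generator does **not** model: CpG-island spatial autocorrelation,
sequence-dependent methylation, imprinted DMRs, batch/technology effects,
phasing errors, and coverage GC bias.  Passing recovery tests therefore
demonstrate the pipeline's correctness under its own assumptions, not its
operating characteristics on real cohorts.

## Problem sizes and calibration

Validation runs use 50 samples × 20k CpGs × 20× per-haplotype coverage
with 30 planted allele-specific events (effect 0.5) for recovery, 30
samples × 10k CpGs for cis-linkage recovery, and 200 replicates of an
80-sample random-call cohort for permutation-test calibration.  The null
bound for path-A calls (10⁻³ per sample-tile) was pinned from event-free
runs at the 50 × 20k scale, where observed rates were 4.1–4.6 × 10⁻⁴.

## Known limitations

- Percentile ranks need a cohort: with very few samples the add-one rank
  is coarse (minimum 1/(1+n_others)).
- The q-curve threshold is a binned heuristic, not a formal FDR control.
- Path-B's separation rule makes its calls sensitive to single extra
  carriers near the z = 5 boundary — intended, since it exists to reject
  dynamic regions.
- The permutation p-value is valid but conservative when shared counts tie
  heavily (small cohorts).
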