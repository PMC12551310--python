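# collapsemask

Identify **collapsed multicopy regions** — segmental duplications, repeats,
transposable elements, paralogous gene families — in population-level
whole-genome sequencing data, directly from a multi-sample VCF, **without
assuming random mating**.

When a genomic sequence is present in two or more copies but the reference
carries only one, reads from all copies map to the same locus ("collapse").
The collapsed locus shows up in a population VCF as excess sequencing depth
(~2x for two copies), an excess of heterozygote calls, and alternative-read
ratios pulled toward 0.25/0.75.  SNPs called inside such regions are
artifacts, and they bias essentially every downstream population-genetic
quantity: diversity (θ_W, θ_π) upward, the inbreeding coefficient F_IS and
population differentiation F_ST downward, Tajima's D and the allele
frequency spectrum toward intermediate frequencies.  `collapsemask`
classifies every biallelic SNP as single-copy or multicopy and emits a BED
mask, so those regions can be excluded (or studied in their own right).

## Method

Three steps, each consuming only what a standard VCF provides
(GT, AD, DP, GQ):

1. **Heterozygosity mixture (EM).**  At a single-copy SNP the expected
   heterozygote frequency is `2·maf·(1−maf)·(1−F_IS)`; at a collapsed SNP
   every minor-allele copy surfaces in a spurious heterozygote, so
   `f(het) ≈ 2·maf`.  The scaled heterozygote frequency `f(het)/2maf` is
   regressed on `(1−maf)` as a two-component beta-binomial mixture fitted
   by Expectation-Maximization; the inbreeding level is absorbed into the
   single-copy component's coefficients, so nothing is assumed about the
   mating system (an estimate `fis_hat` falls out of the fit).  SNPs are
   labeled SINGLE / MULTI / UNCERTAIN by per-SNP log-likelihood ratio.
2. **Read-ratio deviations.**  At true heterozygotes alternative reads are
   ~Binomial(N, 0.5).  Per SNP, reads are pooled over heterozygous
   individuals into `z = (A − N/2)/sqrt(N/4)` and compared to the
   *empirical* two-sided 95% interval of z at the SNPs step 1 classified as
   single-copy (which absorbs the overdispersion of real read ratios).
   UNCERTAIN SNPs outside the interval become MULTI.
3. **Haplotype elongation.**  Multicopy SNPs cluster in haplotypes.  A
   two-component geometric mixture of inter-seed distances yields a distance
   threshold; regions are elongated outward from seed SNPs, absorbing
   neighbors whose carrier individuals (heterozygous at the nearest seed)
   show ≥1.5x depth excess, and breakpoints are placed at mid-distances,
   capped at half the threshold.  The result is a disjoint set of multicopy
   regions; SNPs inside are MULTI, everything else is SINGLE.

The package also ships a synthetic-cohort generator (mosaic genomes with
known duplicated haplotypes, inbreeding, read sampling and a GATK-like
caller) and a small population-genetics harness (θ_W, θ_π, Tajima's D,
F_IS, Weir–Cockerham F_ST, AFS/jAFS) used to quantify the biases and their
correction.  See `docs/methods.md` for the full model.

## Worked example

Simulate a small cohort (40 diploids, 200 kb, 10% duplicated sequence,
random mating), mask it, and measure the effect:

```bash
collapsemask simulate --out sim --n-ind 40 --length 200000 --seed 3
# simulated 1062 SNPs to sim
collapsemask mask --vcf sim/cohort.vcf --out mask --min-gq 0 --min-depth 2 --seed 3
# wrote mask for 1062 SNPs (34 regions) to mask
collapsemask evaluate --classifications mask/classifications.tsv \
    --truth-snps sim/truth_snps.tsv --out eval.json
# {"n_snps": 1062, "recall_total": 0.9727, "recall_single": 0.9883,
#  "recall_multi": 0.9317}
collapsemask stats --vcf sim/cohort.vcf --out stats \
    --mask mask/mask.bed --truth sim/truth.bed --min-gq 0 --min-depth 2
```

`stats/stats.tsv` (abridged):

| set          | S    | theta_w  | theta_pi | tajimas_d | fis     |
|--------------|------|----------|----------|-----------|---------|
| all          | 1062 | 0.00108  | 0.00135  | 0.879     | −0.204  |
| masked       | 780  | 0.00079  | 0.00091  | 0.507     | −0.0003 |
| truth_single | 769  | 0.00078  | 0.00089  | 0.485     | −0.0009 |

Reading: the unfiltered SNP set overestimates diversity by ~40–50% and
shows a strongly negative inbreeding coefficient (−0.204, a spurious
heterozygote excess) relative to the true single-copy subset; after
excluding the inferred mask, every statistic sits essentially on the
truth-single value.  97.3% of SNPs were labeled correctly (98.8% of
single-copy, 93.2% of multicopy SNPs).

On real data you would run only
`collapsemask mask --vcf cohort.vcf.gz --out outdir` (defaults: GQ ≥ 30,
DP ≥ 5, ≤10% missing per site) and subtract `outdir/mask.bed` from
downstream analyses.

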