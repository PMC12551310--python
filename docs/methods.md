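# Methods

## Problem and model

Genomic sequence present in two or more copies (segmental duplications,
transposable elements, paralogous gene families) collapses onto a single
locus when short reads are mapped to a reference carrying one copy.  A
collapsed locus shows three signatures in a population VCF: excess sequencing
depth (~2x for two copies), spurious heterozygote calls, and intermediate
read ratios (0.25/0.75 when one of two collapsed copies is heterozygous,
~0.5 at fixed inter-copy differences).  `collapsemask` classifies every
biallelic SNP as SINGLE (single-copy) or MULTI (multicopy) and emits a BED
mask of multicopy regions, without assuming random mating.

### Step 1 — heterozygosity mixture

At a single-copy SNP the expected heterozygote frequency is
`2·maf·(1−maf)·(1−F_IS)`.  At a collapsed SNP every copy of the minor allele
surfaces in a (possibly spurious) heterozygote, so `f(het) ≈ 2·maf`.
Dividing by `2·maf` gives the scaled heterozygote frequency
`s = f(het)/2maf ∈ [0, 1]`:

* single-copy component: `s_K(maf) = b0 + b1·(1−maf)` — the inbreeding
  coefficient is absorbed in the coefficients (`b0 ≈ 0`, `b1 ≈ 1−F_IS`);
* multicopy component: a constant `s_D` close to 1.

The observation at SNP *i* is `k_i = n_het` successes out of
`m_i = n_het + 2·n_hom_minor` trials (the minor-allele copy count; `k/m` is
exactly the scaled heterozygote frequency).  Each component is beta-binomial
with its own intra-class correlation `rho`, absorbing sequencing error,
mapping bias and interlocus gene conversion.  The two components are fitted
by EM: the E-step recalibrates per-SNP multicopy weights from the component
densities and the mixing proportion; the M-step maximizes each component's
weighted log-likelihood with L-BFGS-B warm-started at the previous solution
(so the total log-likelihood is non-decreasing, checked to 1e-6).  SNPs are
classified from `llr = log f_D − log f_K`: above the upper threshold MULTI,
below the lower threshold SINGLE, otherwise UNCERTAIN.

Numerical choices (all exposed as parameters):

* **Weight initialization** — residual distances of `s` from the two
  asymptotic lines, `W = d_K/(d_K + d_D)` clipped to [0.05, 0.95].  The
  single-copy line uses a provisional genome-wide inbreeding estimate
  `F0 = 1 − H_obs/H_exp` (clipped to [0, 0.95]); starting from the
  random-mating line under strong inbreeding assigns half of the
  single-copy SNPs to the wrong component and the mixture collapses.
* **Component bounds** — `s_D ∈ [0.5, 1)`: the collapsed line is ~1 by
  theory, and an unbounded mean lets the overdispersed multicopy component
  slide onto the inbred single-copy line (label switching).
  `b0 ∈ [−0.3, 0.3]` (the single-copy line passes through the origin),
  `b1 ∈ [−0.1, 1.2]`, `rho ∈ [1e-6, 0.95]`.  The single-component fit is
  restarted from several slope values (1.0, 0.5, 0.1 — no inbreeding to
  strong inbreeding) because the identity-scale likelihood has flat clipped
  plateaus.
* **Rare sites** — SNPs with `m < 3` are parity-degenerate (`k ≡ m mod 2`;
  a lone minor copy is always in a heterozygote) and carry no usable
  signal.  They are excluded from the likelihood and labeled UNCERTAIN at
  this step; including them biases the inbreeding estimate by ≈ −0.05 at
  `F_IS = 0.9`.
* **One-sided classification** — excess heterozygosity is a one-sided
  signature; a SNP whose `s` lies below the fitted single-copy line is
  never labeled MULTI at this step, however the overdispersed multicopy
  density ranks it.
* **LLR thresholds** — default (−2, +3) in natural-log units.  The
  published step behavior (≈41%/51% of single-/multicopy SNPs confidently
  classified under random mating with ≈0.5% error) is reproduced at these
  values; a symmetric ±2 admits the coincidence class in which all ~20–30
  minor copies of a maf ≈ 0.1–0.15 SNP happen to sit in heterozygotes
  (probability `e^−λ` with λ the expected minor-homozygote count, so common)
  at several times that error rate.  Ties at a threshold stay UNCERTAIN.
* `fis_hat = 1 − (b0 + b1)`, the single-copy mean relationship evaluated at
  `maf → 0`, clipped to [−1, 1].

### Step 2 — read-ratio deviations

For each SNP, reads are pooled over heterozygous individuals and
standardized against Binomial(N, 1/2):

    z = (A − N/2) / sqrt(N/4)

with `A` the summed alternative reads and `N` the summed reads (sites with
`N < 4` are skipped).  The rejection region is the empirical two-sided 95%
interval (type-7 linear-interpolation quantiles) of `z` at EM-classified
single-copy SNPs — not ±1.96 — because real read ratios are overdispersed
relative to binomial and the overdispersion grows with `N` (locus-level
mapping bias is shared across individuals).  At least 200 single-copy
z-scores are required.  Only UNCERTAIN SNPs with `z` outside the interval
are promoted to MULTI; EM labels are never overwritten.

### Step 3 — haplotype elongation

SNPs labeled MULTI by steps 1–2 are seeds.  Consecutive inter-seed distances
are a mixture of short within-haplotype and long between-haplotype spacings;
a two-component geometric mixture (closed-form EM, 500 iterations, tolerance
1e-10) yields a distance threshold at the posterior crossing point
`d* = 1 + log((1−π)p₂ / πp₁) / log((1−p₁)/(1−p₂))`.  A degenerate fit
(component weight < 1e-3 or success-probability ratio < 1.5) falls back to a
configurable fixed threshold (default 1000 bp) with a warning.

Elongation scans outward from each seed (left and right passes are
independent and symmetric; seed chains connected in either direction merge):

a. an adjacent seed merges into the region (subject to the distance budget
   below);
b. a non-seed focal SNP within threshold/2 of the last seed is absorbed if
   the carrier set — individuals heterozygous at the nearest seed, ties to
   the upstream seed; all covered individuals if the seed has no
   heterozygote left — has mean depth ≥ 1.5x the genome-wide mean at the
   focal SNP;
c. a focal SNP without depth excess labeled SINGLE closes the region: the
   breakpoint is the mid-distance between the previous SNP and the focal
   SNP when no SNPs were skipped, and is anchored at mid(last seed, seed's
   first neighbor) otherwise, so skipped SNPs stay outside the mask;
d. an UNCERTAIN focal SNP without depth excess is skipped while the mean
   distance of the skipped chain from the last seed stays below the
   threshold; otherwise the region closes as in (c);
e. every breakpoint is capped at threshold/2 from the last seed (contig
   ends included).

Every SNP inside a final region is MULTI; UNCERTAIN SNPs outside all regions
default to SINGLE (the mask complement), so final labels are binary.
Breakpoint coordinates are floored onto the 0-based half-open BED axis.

## Synthetic cohorts

The generator emulates, at the VCF level, the end product of the chain
forward-simulation → read simulation → mapping → GATK calling.  Defaults are
the main study conditions: 100 diploids, 10x mean depth, ~1 Mbp, 10%
collapsed duplicated sequence, random mating.

* **Layout** — duplicated haplotypes with exponential lengths (mean 1 kb,
  clipped to 0.1–10 kb) tiled at exponential gaps until the collapsed
  duplicated length reaches `dup_fraction × genome_length` (~100 haplotypes
  at 10% of 1 Mbp, ~500 at 50%, matching the reported simulated counts).
* **Single-copy SNPs** — density `theta·a_k` per bp (`a_k = Σ 1/i`,
  `k = 2n`), frequencies from the neutral 1/p law on
  [1/(4n), 1−1/(4n)]; `theta` defaults to 0.001/bp and is divided by
  `1 + F_IS` (inbreeding lowers effective size), which reproduces the
  reported SNP-count ratio between random-mating and inbred runs.
  Genotypes: with probability `F_IS` an individual is autozygous (homozygous
  by descent), else Hardy-Weinberg.
* **Duplications** — 70% fixed in the population, 30% segregating at a
  uniform population frequency; an individual carries `d ∈ {0,1,2}` extra
  copies (autozygosity applies).  Within a duplication: fixed inter-copy
  differences at 0.005/bp give every carrier alt-read fraction `d/(2+d)`;
  variation segregating on the original or the duplicated copy gives
  dose/(2+d) fractions (0.25/0.75 signatures).
* **Reads** — depth ~ Poisson(mean_depth·(2+d)/2); alternative reads
  beta-binomial around the expected fraction with per-genotype rho 0.005, a
  per-site logit-normal mapping bias (sd 0.1, shared across individuals —
  the component that makes pooled-z overdispersion grow with read count)
  and base error 0.001 (Q30).
* **Calling** — default GATK-like: binomial genotype likelihoods with a
  Hardy-Weinberg prior at the pooled-read allele-frequency estimate;
  GQ = phred gap between the two best genotypes, capped at 99.  A raw
  alt-ratio threshold caller (`caller_mode="threshold"`) is available.
* Identical parameters and seed give byte-identical VCFs.

Simulated cohorts are analyzed with `min_gq=0, min_depth=2,
max_missing=0.1`: the whole-genome defaults (GQ ≥ 30, DP ≥ 5) are tuned to
>20x empirical data and would mask about half of all genotypes at 5–10x
Poisson depths.

**What the generator does not emulate** — read-level mapping (soft-clipping,
multi-mapping), interlocus gene conversion (collapsed substitutions never
erode), more than two collapsed copies, indels, linkage between nearby SNPs
beyond the shared duplication, and reference bias beyond the symmetric
locus-level ratio shift.  Passing recall figures therefore show that the
three steps exploit the collapse signatures correctly at realistic
signal-to-noise, not that the numbers transfer verbatim to any particular
empirical pipeline.  Two knock-on effects are visible in the acceptance
grid: SNPs on low-frequency segregating duplications (the uniform 30% class)
are genuinely undetectable here — carriers of one extra copy sit below the
1.5x depth bar — which depresses multicopy recall at random mating by ~1-4 pp
relative to the published grid (largest at 50% duplications, where inflated
genome-wide mean depth also disables the depth-excess rule); and the fully
diverged fixed differences make the inbred 50%-duplication setting easier
than its published counterpart by ~3-5 pp.

## Population-genetic statistics

Standard estimators on diploid genotype matrices (two sequences per
individual; missing genotypes reduce the per-site sequence count):
Watterson's `theta_W = S/(a_k·L)`; unbiased pairwise diversity
`theta_pi = Σ 2p̂q̂·n/(n−1) / L`; Tajima's D with the standard variance
normalizer; `F_IS = 1 − ΣH_obs/ΣH_exp` with the 2n/(2n−1) small-sample
correction; Weir–Cockerham two-population F_ST from per-site variance
components; AFS (folded and unfolded; sites with missing data projected
multiplicatively) and the joint AFS count matrix whose marginals equal the
per-population spectra.

## Problem sizes

The acceptance script averages three ~1 Mbp replicates per setting
(~6,000–12,000 SNPs each; one replicate per setting runs through an actual
VCF file round trip).  The test suite runs one replicate per grid setting
and four bias-experiment levels (5/20/35/50% duplications); unit tests use
40-diploid, 300 kb cohorts.  These sizes were chosen so the full suite
completes in minutes on one core while keeping ≥2,000 SNPs per fit, well
above the 500-SNP floor the EM requires.

## Known limitations

* Copy number > 2 is not modeled; read ratios drift toward 0.5/k and the
  heterozygosity line stays at 1, so higher copy numbers are detected but
  not genotyped.
* The EM has no information at very rare SNPs (m < 3); their recovery relies
  entirely on read ratios and clustering.
* The distance threshold assumes geometric-like spacing mixtures; strongly
  non-stationary SNP densities (e.g. RAD-seq) violate this.
* `fis_hat` reflects the heterozygosity actually observed in the VCF; caller
  het-undercall at low depth surfaces as apparent inbreeding.
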