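# Methods

This note documents the statistical procedures implemented in `rohsignal`,
the defaults chosen where several reasonable conventions exist, and what
the synthetic-data experiments do and do not demonstrate.

## Data model

All stages operate on a samples × loci matrix of diploid alternate-allele
dosages (0/1/2, with −1 for missing). Phase is discarded on VCF read — no
stage uses it. Half-missing genotype calls (one known allele) are treated
as missing. Coordinates are 1-based inclusive internally (VCF convention);
BED export converts to 0-based half-open at the single exporting function.
Chromosome labels are opaque strings; an optional whitelist defines the
autosomes, since label spellings vary between references.

## Filtering

Order: SNP call rate (default ≥ 0.95) → individual call rate on the
surviving SNPs (default ≥ 0.80) → monomorphic removal (a locus is
monomorphic when its non-missing calls carry a single allele; missing
calls are ignored) → LD pruning. SNP-rate-first is a convention choice;
the stages are exposed separately so the order can be flipped.

**LD pruning.** The measure is the squared Pearson correlation of dosage
vectors over pairwise-complete samples; a zero-variance (window-
monomorphic) locus is treated as r² = 0 because it cannot be in LD.
Classic sliding-window pruners step a 50-SNP window by 5 SNPs and drop one
locus of each offending pair, but a stepped scan can miss pairs that are
46–49 apart in the retained list when the step never aligns a window over
both. `rohsignal` instead removes the later (larger-position) locus of any
retained pair closer than `window_snps` in the retained list, sweeping
left to right and iterating to a fixpoint. The output therefore satisfies
an exhaustive audit: no retained pair that fits in *any* placement of the
window exceeds the threshold. This is deterministic for a fixed input
order and at least as strict as the stepped variant. (PLINK's `--indep`
uses a VIF criterion; the pairwise-r² semantics implemented here follow
the common `--indep-pairwise` reading. VIF pruning is out of scope.)

## Diversity statistics

Let a locus in a population have `n` non-missing allele copies and
alternate frequency `p`.

- **π** per locus is the unbiased pairwise diversity `2p(1−p)·n/(n−1)`;
  the population value is the mean over loci with n ≥ 2. This equals the
  brute-force mean proportion of differences over all distinct pairs of
  non-missing allele copies, which the tests verify to 1e−12.
- **θ (Watterson)** is `S/(a_{n−1}·L)` with S the segregating-site count,
  L the callable loci and `a_m = Σ_{k≤m} 1/k`. With missing data n varies
  by locus; the default uses the median per-locus copy count for the
  harmonic number, with exact per-locus harmonic weighting behind a flag.
  (The classical definition of θ via "differences between two random
  haplotypes" describes π; the Watterson estimator is what diversity
  pipelines report as θ, and is what is implemented.)
- **Raw Tajima's D** is reported as `π − θ`, *not* the classical
  variance-normalised statistic. Negative values indicate an excess of
  rare alleles (sweeps, expansion), positive values an excess of
  intermediate-frequency alleles. The classical normalised D is available
  separately (`tajima_d_classical`) and kept out of the main table.
- **χ² contrast.** `(πL − θL)²/(θL)` against χ²₁, a goodness-of-fit-style
  contrast of the two diversity totals; reported as `pi_theta_chi2`, a
  package-specific construction, with p missing when θ = 0.
- **He** is the per-individual heterozygous-call fraction
  `(nH/nind)·(nsnps/ntotal)`, averaged over the population's individuals.
  `ntotal` (genome length covered) defaults to `nsnps`, making the
  correction factor 1; override it to express He per covered base.
- **MAF** is the folded frequency `min(p, 1−p) ≤ 0.5`. Because some
  published "MAF" columns exceed 0.5, the summary also emits the unfolded
  mean alternate-allele frequency for comparison.
- **Private alleles** count (locus, allele) pairs observed in exactly one
  population; both the raw count and the per-SNP rate are reported.

## Population structure

**Weir–Cockerham Fst.** Per locus the 1984 variance components a (among
populations), b (among individuals within populations) and c (within
individuals) are computed from per-population sample sizes, allele
frequencies and observed heterozygote proportions, with missing data
handled by per-locus population sample sizes. Multi-locus estimates
combine as ratio of sums Σa/Σ(a+b+c) — the convention of StAMPP and most
Fst software — and pairwise values get a percentile CI from a seeded
bootstrap over loci (default 1000 replicates). Loci informative in fewer
than two populations are excluded. Negative point estimates (sampling
noise around zero) are kept in tables but clamped to 0 in distance
matrices used for tree building.

**AMOVA.** Allele-level three-stratum decomposition: each called genotype
contributes two allele copies, and per-locus nested sums of squares
(among populations / among individuals within populations / within
individuals) are accumulated across loci, with variance components solved
from the standard expected-mean-square coefficients (copies-based n₀ for
unequal population sizes). Allele-level rather than genotype-level
distances were chosen so that the "within individuals" stratum is
well-defined. Significance of the among-population component comes from
permuting individuals across populations (default 1000, seeded), with the
`(exceedances + 1)/(n_perm + 1)` correction. The tests verify the sums of
squares against an independent pairwise-squared-difference partition.

**Trees and ordination.** Neighbor joining is Saitou–Nei via scikit-bio
(negative branch lengths clamped to zero); on additive matrices the
patristic distances reproduce the input exactly, which the tests assert.
PCoA is classical scaling — eigendecomposition of the double-centred
−½d² matrix — with axes ordered by descending eigenvalue and
negative-eigenvalue axes excluded from coordinates but reported.

## Runs of homozygosity

The scanner follows the sliding-window logic of PLINK's `--homozyg` with
the window parameterisation common in chicken ROH studies: 50-SNP
windows, ≤ 1 heterozygote and ≤ 5 missing calls per "homozygous" window,
a SNP is ROH-eligible when ≥ 5% of the windows covering it are homozygous
(the window-threshold reading of the 0.05 parameter), and runs break at
heterozygous SNPs, at non-eligible SNPs, and at inter-SNP gaps over
1000 kb. Windows are anchored so every SNP is covered by at least one
window; chromosomes shorter than 50 SNPs are scanned with a single
truncated window. Segment coordinates are the first and last SNP of the
run. Segment-level filters default to ≥ 50 SNPs and ≥ 1000 kb; a maximum
kb-per-SNP density filter exists but is **disabled by default** because at
reduced-representation densities (~80 kb/SNP) any PLINK-like default
would reject every segment.

`F_ROH` is total ROH length divided by the genome size, default
930,820,000 bp (the chicken autosome total). ROH incidence counts, per
SNP, the individuals whose segments cover it, divided by **all**
individuals in the dataset; a per-population denominator is available via
subsetting. ROH islands are the loci at or above the top-1% incidence
quantile, ties included — so a constant incidence profile returns every
locus, the documented degenerate behaviour.

LD decay bins all intra-chromosomal pairs within a maximum distance
(default 1000 kb) and reports mean r² per distance bin; the expected
floor for unlinked loci is the finite-sample value ≈ 1/n.

## Selection scan

Per-locus multi-population Weir–Cockerham Fst is computed twice: the
standard estimator (reported) and the variant without the finite-sample
correction, which stays non-negative and is the quantity whose neutral
distribution is modelled — the approach popularised by OutFLANK. The
neutral model is `Fst·df/F̄st ~ χ²_df`. Loci with pooled expected
heterozygosity < 0.1 are excluded (their estimates are noisy and biased),
the top and bottom 5% of the remaining Fst values are trimmed, and
(df, F̄st) are estimated by maximum likelihood on the doubly-truncated
density, so outliers in either tail cannot drag the fit. Initialisation
uses the moment estimates df₀ = 2m²/v, F̄st₀ = m of the trimmed sample;
optimisation is Nelder–Mead in log-parameters; non-convergence or
degenerate (constant) input raises rather than returning a bad fit.
P-values are right-tail only (the scan seeks unusually *high*
differentiation); non-positive Fst maps to p = 1.

Top-fraction selection uses quantile thresholds with ties included, for
both the lowest-p set (default 1%) and the highest-incidence set (default
5%); a signature is a locus in both sets. Annotation is against local BED
or GFF intervals only: overlapping features within ± window_kb and the
nearest feature with its distance.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
at the scale of the motivating study design: 11 populations with sizes
(8, 12, 12, 10, 11, 10, 7, 12, 11, 16, 10) — 119 individuals — 12,000
bi-allelic SNPs placed uniformly over ten chicken-like chromosomes
totalling 930.82 Mb, 2% missing calls.

- **Divergence** is Balding–Nichols: ancestral frequencies
  Uniform(0.05, 0.95); each population draws Beta(p(1−F)/F, (1−p)(1−F)/F)
  with its own F. Defaults span 0.10–0.80, the higher values representing
  strongly drifted inbred lines; the Weir–Cockerham estimator recovers
  pairwise F to ±0.02 at 5000 loci, which is the model's defining
  property. The model has no coalescent realism (no shared drift
  topology, no mutation-rate variation); it is the minimal model with a
  direct Fst dial.
- **Inbreeding** is implanted, not simulated through pedigrees: per
  individual, disjoint intervals (default 5–20 Mb each) totalling the
  population's target genome fraction (defaults 0.02–0.45) are forced
  homozygous, heterozygotes flipping to 0 or 2 by a fair coin. This gives
  exact truth intervals for boundary-accuracy tests, at the cost of
  realism in ROH length distributions and in the correlation between
  inbreeding and allele frequencies. Populations with high divergence F
  also develop *spontaneous* long homozygous stretches (most loci near
  fixation), which is realistic for inbred lines but means ROH incidence
  in such populations is not fully under the generator's control.
- **Planted islands** force a chosen interval homozygous in a chosen
  carrier subset, giving exact expected incidence (e.g. 64 of 119
  carriers → 53.78%).
- **Planted outliers** are defined as loci that *are* high-Fst: the
  Balding–Nichols draw at F × multiplier is rejection-sampled until the
  locus is polymorphic overall (pooled frequency in [0.15, 0.85]) and its
  realized between-population variance is at least half the amplified
  target. Without this, a large fraction of "plants" would fix identically
  in every population and carry no signal at all, making truth labels
  meaningless for recall measurement. The contract is therefore: a truth
  outlier is a locus with realized, not merely attempted, divergence.
- **LD** is off by default (independent loci); when requested, consecutive
  blocks are drawn from small per-population haplotype pools, giving
  within-block r² for pruning and decay tests. The decay shape is
  block-wise, not the smooth recombination-driven curve of real data.
- **Missingness** is uniform at random — no call-rate structure per
  individual or locus beyond the binomial.

All randomness flows from a single integer seed through numpy's PCG64;
outputs (VCF, popmap, truth JSON) are byte-for-byte reproducible.

What passing the recovery tests shows: the estimators correctly measure
the quantities they claim on data satisfying their assumptions (HWE
within populations, independent loci, dosage-accurate genotypes). What it
does not show: robustness to genotyping error, allele dropout,
non-uniform missingness, or LD misspecification in real
reduced-representation data.

## Problem sizes and numerical choices

Default problem sizes — 12,000 loci for study-scale runs, 5000 loci for
two-population recovery experiments, 1000 bootstrap/permutation
replicates — were chosen so the full pipeline completes in about a minute
on a single CPU while keeping Monte-Carlo error well inside the asserted
tolerances. Quantile thresholds use numpy's default linear interpolation;
ties at a threshold are always included. Bootstrap and permutation
p-values use the +1 correction to avoid zero. The neutral fit requires
≥ 100 usable loci. Degenerate inputs (θ = 0, single population,
zero-variance dosages, empty distance intersections) raise errors or
return documented missing values rather than silently producing numbers.

## Known limitations

- Pairwise Fst bootstrap resamples loci only; individual-level
  uncertainty is not propagated.
- The AMOVA permutation tests only the among-population stratum.
- The raw `π − θ` difference has no variance normalisation, so its scale
  depends on the SNP panel; compare only within a dataset.
- The ROH scanner is a faithful window heuristic, not a probabilistic
  identity-by-descent model; very short or SNP-sparse ROH below the
  segment filters are invisible by design.
- Multi-allelic sites are dropped, not decomposed.
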