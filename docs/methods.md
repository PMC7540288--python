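# Methods

This note documents the models, estimators and design choices behind
`erconcord`, and what the synthetic experiments do and do not establish.

## Data model

All analyses run on a `CountTensor`: read counts of two alleles per SNP ×
replicate × time point. Sync files are reduced to the two most frequent
bases (summed over all samples); `N` and deletion counts never enter the
depth. Positions are 1-based. The mapping from sync columns to
(replicate, generation) is always supplied explicitly in the configuration
— deposited files document their column order externally, and guessing it
silently would be worse than failing.

**Polarization.** The tracked ("rising") allele is the one whose frequency
change from generation 0 to the last generation, averaged over replicates,
is ≥ 0. Exact ties track the allele that is minor at generation 0, which
makes polarization deterministic and idempotent. Depth is untouched.

**Segregating universe.** Most similarity analyses use the SNPs that
segregate (0 < frequency < 1, depth > 0) in *every* replicate and
generation. This is the universe that windows are built from and that the
Jaccard null resamples; a SNP fixed in a single replicate leaves it.

## Wright–Fisher simulator

Non-overlapping generations, diploid census N (default 1,000), R = 10
replicates, generations 0–60 recorded every 10th.

**Selection.** Multiplicative codominance: each copy of the rising allele
multiplies fitness by (1+s), so genotype fitnesses are ((1+s)², 1+s, 1)
and the deterministic recursion p′ = p(1+s)/(1+ps) is exactly linear on
the logit scale with slope ln(1+s) per generation. This exactness is used
twice: the simulator's closed-form oracle tests, and the inverse estimator
ŝ = e^slope − 1. Fitness combines multiplicatively across target loci
(no epistasis, no dominance parameter beyond the codominant scheme).

*Scale convention.* Literature selection coefficients for E&R sweeps are
usually stated on the homozygote with h = 0.5 (heterozygote 1 + s/2). The
translation to this package's per-copy scale is
`per_copy_s(S) = sqrt(1+S) − 1 ≈ S/2`. The study-condition experiments
(winner's curse, linked sweeps with "s = 0.05") pass the homozygous value
through this translation; quantities named `s` elsewhere in the API are on
the per-copy scale. Mixing the scales doubles the effective selection
intensity and, e.g., saturates the winner's-curse design.

**Unlinked mode.** Each locus iterates deterministic selection followed by
binomial drift over 2N gene copies (1.5N in the optional X-linked mode).
Neutral loci draw starting frequencies uniformly from (0.05, 0.95) —
a flat stand-in for an ascertained SNP panel, not a population SFS;
selected loci start at p0 (default 0.10).

**Linked mode.** Individuals are haplotype pairs over all polymorphic
founder sites. The founder pool (default 189 haplotypes) is generated by a
coalescent with recombination (msprime) at a deliberately small Ne
(default 1,000) so that the pool carries the long-range LD of a
laboratory founder population rather than of a wild population; it is a
synthetic stand-in for an experimentally phased founder panel. Each
generation, two parents per offspring are drawn with probability
proportional to fitness; gametes recombine with a Poisson number of
crossovers (mean = map length in Morgans, no interference), positions
inverse-sampled from the cumulative genetic map (constant rate, default
2 cM/Mb, or a user map). Selection targets are the sites with founder
frequency closest to p0, one per genome bin. All sites' frequencies are
recorded, so hitchhikers are first-class.

**Pool-seq sampling.** Per site × replicate × time point: depth ~
Poisson(λ) (default λ = 80), rising-allele count ~ Binomial(depth, true
frequency). This models pooling the whole census (reads sample the
population allele frequency directly); there is no separate
individual-subsampling stage.

**Synthetic blocks.** `make_blocks` emulates haplotype blocks obtained by
trajectory clustering: a block holds its target plus the sites within
`window_bp` (default 100 kb) whose replicate-mean frequency change over
the run is ≥ 0.10 *and* whose frequency-change profile across replicates
and generations correlates with the target's at ≥ 0.9. The tight
correlation mirrors the fact that reconstructed blocks are, by
construction, sets of SNPs riding the same sweep in the same replicates.

## Temporal Ne

Waples-family moment estimator on F_c = (x−y)²/(z−xy), z = (x+y)/2,
between generations 0 and t. Read sampling adds an expected 1/D0 + 1/Dt
to F_c (whole-census pooling); when only n of N individuals are pooled the
two-stage term 1/(2n) + 1/D − 1/(2nD) applies per time point
(`pool_size=n`). The corrected drift signal gives
N̂e = −t / (2 ln(1−F′)). Numerator and denominator are summed over SNPs
before the ratio (ratio-of-sums): a bias check against the simulator
(neutral, N = 1,000, t = 20, λ = 80, 10⁵ SNPs) recovers N within ~2%,
whereas averaging per-SNP ratios is 8–10% high (Jensen bias on skewed
frequency spectra); the per-SNP variant remains available via
`average="per_snp"`. Estimates with F′ ≤ 0 are flagged unbounded (drift
below sampling noise). Autosomes and the X are estimated separately; CMH
nulls use the cross-replicate arithmetic mean, Fisher nulls per-replicate
values.

## Candidate scan

Classical 1-df CMH chi-square on raw read counts, no continuity
correction; strata with a zero margin drop out, and a SNP with no usable
stratum gets p = 1. Fisher's exact test (two-sided, conditional) per
replicate. SNPs fixed in every replicate at the focal generation are not
tested there.

The neutral null re-simulates every observed SNP: starting frequency =
pooled empirical generation-0 frequency, binomial drift at 2N̂e copies for
t generations per replicate, Pool-seq read draws at the observed depths of
both time points, then the identical test. The threshold is the largest
cutoff c with (#null ≤ c × |obs|/|null|) / (#obs ≤ c) ≤ q (default
q = 0.05); if no cutoff qualifies the candidate set is empty — on fully
neutral data this is the expected outcome, not an error. The null ensemble
defaults to one replicate of the observed SNP count; thresholds are
recomputed per time point because N̂e(0, t) changes with t.

The headline candidate set is the CMH set; Fisher per-replicate sets are
computed as diagnostics and not intersected into it.

## Windows and rank overlap

Windows are consecutive runs of `window_snps` everywhere-segregating SNPs
per chromosome (chromosome 4 excluded; trailing remainders dropped). The
enrichment null places the observed number of windowed candidates
uniformly without replacement onto the windowed SNPs — drawn per
iteration as a multivariate hypergeometric over window sizes — and the
per-window threshold is the ceiling-index 99th-percentile order statistic
of 1,000 null counts; enrichment uses ≥. Per-window null distributions
(rather than one global threshold) stay correct if a robustness rerun uses
base-pair windows of unequal SNP content.

Rank-overlap curves rank a window's candidates by p-value (ties broken by
genomic position, for determinism) and report |top-r(t₁) ∩ top-r(t₂)|/r.
The reference curve min(r, n_earlier)/r is the overlap expected if every
late-generation variant were recapitulated earlier.

## Concordance

Jaccard significance resamples two sets of the observed sizes uniformly
without replacement from the universe. Under that null the overlap is
exactly hypergeometric, so the draw is implemented as
m ~ Hypergeom(U, |a|, |b|), J_null = m/(|a|+|b|−m) — identical
distribution to explicit set resampling at a fraction of the cost.
p = (1 + #{J_null ≥ J_obs})/(1 + n_boot), BH-adjusted across the 15
time-point pairs (the correction method is an assumption; the analysis it
mirrors names BH only for its feature tests). Small candidate sets make
the null J heavily discrete, so these p-values are conservative there.

"Fixed" in the fixation ratio means the rising allele at frequency 1 in at
least one replicate at the next sampled generation — one fixed replicate
is what removes a SNP from the segregating-in-all universe.

## Blocks, EDHAs and features

Blocks with < 90% of members among final-generation candidates are
excluded (strict threshold). HADR is |block ∩ candidates(t)|/|block|.
EDHA flagging runs k-means on HADR row-vectors with k from the Tibshirani
gap statistic (uniform bounding-box reference, B = 50, first-SE rule;
k can be overridden), and the EDHA cluster is the one with maximal mean
HADR at generation 20 — a formalization of "elevated early discovery";
k = 1 means no EDHAs. Hierarchical clustering (Ward) and a 2-component
PCA are emitted as concordant diagnostics, not decision-makers.

Block selection coefficients fit logit(p) against generation by least
squares on the block's member-mean trajectory, per replicate, using
interior points only; ŝ = e^slope − 1, exact for the deterministic
recursion. Replicates whose frequency change is below `afc_threshold`
(default 0.10; 0.05/0.15/0.20 reported for robustness) are excluded so
non-responding replicates do not drag ŝ down; with no qualifying
replicate the block's ŝ is undefined and the block drops out of that
contrast. s20 uses the sampled generations in [0, 20] (i.e. 0, 10, 20),
s60 all of [0, 60]; r_s = s20/s60 needs s60 ≠ 0. Feature contrasts
(length, starting frequency, recombination rate from an
overlap-length-weighted map average, s20, s60, r_s, rising-replicate
counts) use two-sided Mann–Whitney tests, BH-adjusted across the family.

## Problem sizes and what the tests show

The test-suite and acceptance experiments run at desk scale, chosen as the
package's own reference configurations: neutral calibration at 10⁵ loci,
winner's curse at 10⁴ loci (all at p0 = 0.1, homozygous s = 0.05), the
linked sweep at 2×10⁴ SNPs / 20 targets / 10 replicates with 500-SNP
windows. At these sizes the qualitative results — calibrated FDR, the
winner's-curse parallelism gap, monotonically increasing
adjacent-generation Jaccard similarity — are stable across seeds; exact
counts are not, and empirical-scale quantities (e.g. candidate counts in
the tens of thousands) require the full deposited data.

The generator emulates drift, selection, linkage and Pool-seq noise. It
does not emulate: variable SNP density and depth heterogeneity along real
chromosomes, reference/mapping artifacts, inversions or other segregating
structural variation, changing environments, or epistasis. Passing tests
therefore validate the statistical machinery under the stated model, not
robustness to those features of real data.

## Numerical choices

- Degenerate CMH (all strata unusable) returns p = 1 with statistic 0.
- The empirical-FDR threshold search is the largest observed p-value whose
  running FDR estimate stays ≤ q (stable under ties by construction).
- The gap statistic guards zero dispersion with a 10⁻¹² floor; identical
  HADR rows short-circuit to a single cluster.
- k-means rows are processed in sorted block-id order with a fixed seed,
  making EDHA flags invariant to input row order.
- Logit fits drop boundary frequencies (0 or 1) rather than clamping.
- All randomness flows from integer seeds through numpy Generators; the
  pipeline derives per-stage seeds from the run seed, so a rerun with the
  same config and seed reproduces every table byte-for-byte.
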