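# erconcord

Temporal concordance analysis for replicated Evolve-and-Resequence (E&R)
Pool-seq time series.

E&R experiments evolve replicate populations in the laboratory and sequence
them as pools at several generations. A central question is how stable the
inferred selection signature is over time: do the outlier SNPs found after
20 generations mean the same thing as those found after 60? `erconcord`
answers this by running the same outlier scan at every sequenced generation
and quantifying how much the resulting candidate sets agree — at the level
of single SNPs, of windows with a fixed number of SNPs, and of haplotype
blocks of linked candidates.

## What it computes

Given biallelic allele counts for S SNPs × R replicates × T time points
(PoPoolation2 `sync` files, or the built-in Wright–Fisher simulator):

1. **Temporal Ne** — a Waples-type moment estimator on the standardized
   frequency change *F_c = (x−y)² / (z−xy)*, *z=(x+y)/2*, corrected for
   pool- and read-sampling noise; *N̂e = −t / (2 ln(1−F_c′))*.
2. **Candidate SNPs** — per time point *t*, a Cochran–Mantel–Haenszel test
   across replicates (strata = replicates, each a 2×2 table of allele ×
   generation {0, t} read counts) plus per-replicate Fisher exact tests.
   Because neither test models drift, the p-value cutoff is set empirically:
   neutral drift at *N̂e* is simulated at the observed starting frequencies
   and read depths, scored with the same test, and the threshold is the
   largest cutoff with estimated FDR ≤ 5%.
3. **Candidate windows** — non-overlapping windows of 5,000 (configurable)
   everywhere-segregating SNPs on the main chromosomes; a window is enriched
   when it holds at least as many candidates as the 99th percentile of a
   random-placement null (1,000 draws without replacement). Rank-overlap
   (ROC-like) curves compare the p-value ranking of a window's candidates
   between time points.
4. **Concordance** — Jaccard indices *J = |A∩B| / |A∪B|* between candidate
   sets of all time-point pairs with resampling p-values (BH-adjusted),
   consistency profiles (fraction of final-generation candidates re-found
   at every generation back to g), and fixation accounting.
5. **Haplotype blocks** — per-block discovery rate
   HADR(t) = |block ∩ candidates(t)| / |block|, k-means clustering of HADR
   trajectories (k by the gap statistic) to flag early-detected blocks
   (EDHAs), block-level selection coefficients from logit-linear trajectory
   fits (ŝ = e^slope − 1, averaged over replicates whose frequency change
   passes a threshold), and EDHA vs non-EDHA feature contrasts
   (Mann–Whitney, BH-adjusted).
6. **Simulator** — replicated Wright–Fisher populations (default: 10
   replicates, census 1,000 diploids, generations 0–60 sampled every 10th)
   in unlinked, linked (founder haplotype pool + recombination map) and
   neutral modes, with Poisson read depth and binomial Pool-seq sampling,
   emitting sync files plus truth tables.

## Worked example

`examples/` holds one short script per capability. The winner's-curse
experiment (`examples/03_winners_curse.py`) simulates 5,000 unlinked loci
that all start at 10% frequency with the same codominant selection
coefficient (s = 0.05 on the homozygote) and scans generation 20:

```
loci: 5000, all with p0=0.10 and homozygous s=0.05
called at generation 20: 3644
mean rising replicates, called loci:   2.69
mean rising replicates, uncalled loci: 1.19
```

Although every locus has identical true parameters, the loci that pass the
significance threshold rose by ≥10% in 2.7 replicates on average versus 1.2
for the rest: conditioning on early significance selects loci that drift
happened to push up in many replicates at once, so short experiments
overstate parallelism.

The concordance example (`examples/04_linked_concordance.py`) runs the full
pipeline on a linked sweep simulation and prints the Jaccard index of
adjacent-generation candidate sets:

```
Jaccard index of candidate-SNP sets:
  gen 10 vs 20:  J = 0.353 *
  gen 20 vs 30:  J = 0.493 *
  gen 30 vs 40:  J = 0.724 *
  gen 40 vs 50:  J = 0.764 *
  gen 50 vs 60:  J = 0.839 *
```

Similarity rises monotonically with time: late generations give the stable
picture of the adaptive architecture.

## Command line

A thin CLI wraps the library for pipeline runs driven by a YAML config:

```bash
erconcord simulate --config cfg.yaml --seed 1 --out simdir
erconcord run-all  --config cfg.yaml --seed 1 --out results_dir
```

All tabular outputs are TSV with headers; every run writes a JSON report
and a provenance sidecar recording parameters and seeds.

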