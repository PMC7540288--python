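"""Concordance of selection signatures across time points.

Runs the full pipeline on a linked sweep experiment (founder haplotype
pool, recombination, Pool-seq sampling) and prints the Jaccard
similarity of candidate sets between time points.  Early pairs of
generations agree much less than late pairs: short experiments see an
unstable subset of the architecture.
"""

import erconcord as ec

cfg = ec.RunConfig(
    out_dir="scratch/example_linked",
    seed=31,
    sim=ec.SimConfig(
        mode="linked", n_loci=6_000, n_targets=8, census_n=500,
        n_replicates=10, s=ec.per_copy_s(0.08), p0=0.10,
        depth_lambda=80.0, genome_length=8_000_000, seed=31,
    ),
    window_snps=300,
    enrichment_iterations=500,
    n_boot=2000,
)
res = ec.run_all(cfg)

jac = res["jaccard"]
snp = jac[jac["level"] == "snp"].set_index(["t1", "t2"])
print("Jaccard index of candidate-SNP sets:")
for pair in [(10, 20), (20, 30), (30, 40), (40, 50), (50, 60)]:
    row = snp.loc[pair]
    star = "*" if row["significant"] else " "
    print(f"  gen {pair[0]:>2} vs {pair[1]:>2}:  J = {row['J']:.3f} {star}")
print("(* = significant vs random sets after BH correction)")
print(
    "-> adjacent-generation similarity grows through the experiment: "
    "the late selection signature is the stable one."
)
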