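"""Haplotype-block discovery rates and early-detected blocks (EDHAs).

Simulates a linked sweep experiment, assigns synthetic haplotype blocks
around each selection target, computes each block's discovery rate
(HADR: the fraction of its member SNPs re-found as candidates) per
generation, and clusters the HADR trajectories to flag blocks that are
already detectable at generation 20.
"""

import numpy as np

import erconcord as ec

# targets span weak to strong selection: strongly selected blocks should
# surface early, weakly selected ones only by the end
s_hom = np.linspace(0.05, 0.16, 10)
cfg = ec.RunConfig(
    out_dir="scratch/example_blocks",
    seed=41,
    sim=ec.SimConfig(
        mode="linked", n_loci=6_000, n_targets=10, census_n=1000,
        n_replicates=10, s=0.1,
        s_array=np.array([ec.per_copy_s(s) for s in s_hom]),
        p0=0.10, depth_lambda=80.0, genome_length=8_000_000, seed=41,
    ),
    window_snps=300,
    enrichment_iterations=300,
    n_boot=1000,
)
res = ec.run_all(cfg)

if "hadr" not in res:
    print("no blocks survived the 90% recovery filter in this run")
else:
    hm = res["hadr"]
    edha = res["edha"]
    print("HADR matrix (blocks x generations):")
    print(hm.round(2).to_string())
    n_edha = int(edha["edha"].sum())
    print(f"\nEDHAs (elevated discovery rate at generation 20): {n_edha}")
    if n_edha and "feature_tests" in res:
        ft = res["feature_tests"].set_index("feature")
        print("\nEDHA vs non-EDHA feature contrasts (BH-adjusted):")
        print(
            ft[["median_edha", "median_other", "p_adj"]]
            .round(3)
            .to_string()
        )
    print(
        "\n-> early-detected blocks tend to rise in more replicates by "
        "generation 20 (rising20); at this toy scale the rank tests are "
        "underpowered, so read the medians, not the p-values."
    )
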