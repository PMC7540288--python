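"""Between-time-point concordance of candidate sets.

Similarity of two candidate sets (SNPs or windows) is the Jaccard index
J = |A ∩ B| / |A ∪ B|.  Its significance is assessed against a resampling
null in which two sets of the observed sizes are drawn uniformly without
replacement from the analysis universe; under that null the overlap is
exactly hypergeometric, which is how the draws are generated.  P-values
across the 15 time-point pairs are Benjamini-Hochberg adjusted.

Two further summaries follow the candidate sets through time: the
*consistency profile* (fraction of final-generation candidates that are
candidates at every generation back to g) and the *fixation ratio*
(fraction of time-t candidates whose rising allele is fixed in at least
one replicate by t+10, removing them from the segregating universe).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .sync_io import CountTensor


def jaccard(a: set, b: set) -> float:
    """|a ∩ b| / |a ∪ b|; two empty sets give 0 by convention."""
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def jaccard_significance(
    a: set,
    b: set,
    universe_size: int,
    n_boot: int = 10_000,
    seed: int = 0,
) -> float:
    """Resampling p-value for an observed Jaccard index.

    Null: |a| and |b| items drawn uniformly without replacement from a
    universe of ``universe_size``; the null overlap m is then
    Hypergeometric(universe_size, |a|, |b|) and J_null = m/(|a|+|b|-m).
    p = (1 + #{J_null >= J_obs}) / (1 + n_boot).
    """
    na, nb = len(a), len(b)
    if na > universe_size or nb > universe_size:
        raise ValueError("set larger than universe")
    j_obs = jaccard(a, b)
    if na == 0 or nb == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    m = rng.hypergeometric(na, universe_size - na, nb, size=n_boot)
    j_null = m / (na + nb - m)
    return float((1 + np.sum(j_null >= j_obs)) / (1 + n_boot))


def similarity_matrix(
    sets_by_gen: dict[int, set],
    universe_size: int,
    level: str = "snp",
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise Jaccard indices with BH-adjusted bootstrap p-values.

    Returns a long-format frame (t1 < t2) with columns level, t1, t2, J,
    p_raw, p_adj, significant.
    """
    gens = sorted(sets_by_gen)
    rows = []
    for i, (t1, t2) in enumerate(combinations(gens, 2)):
        a, b = sets_by_gen[t1], sets_by_gen[t2]
        rows.append(
            {
                "level": level,
                "t1": t1,
                "t2": t2,
                "J": jaccard(a, b),
                "p_raw": jaccard_significance(
                    a, b, universe_size, n_boot=n_boot, seed=seed + i
                ),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        rej, p_adj, _, _ = multipletests(
            df["p_raw"].to_numpy(), alpha=alpha, method="fdr_bh"
        )
        df["p_adj"] = p_adj
        df["significant"] = rej
    return df


def consistency_profile(sets_by_gen: dict[int, set]) -> pd.DataFrame:
    """Fraction of final-generation candidates consistently re-detected.

    For each generation g below the final one: the fraction of final-
    generation members present in *every* set from the final generation
    down through g.  Fractions are non-increasing as g decreases.
    """
    gens = sorted(sets_by_gen)
    final = gens[-1]
    ref = sets_by_gen[final]
    rows = []
    running = set(ref)
    for g in reversed(gens[:-1]):
        running &= sets_by_gen[g]
        rows.append(
            {
                "down_to_generation": g,
                "fraction": len(running) / len(ref) if ref else 0.0,
                "n_consistent": len(running),
                "n_reference": len(ref),
            }
        )
    return pd.DataFrame(rows)


def fixation_ratio(
    ct: CountTensor, sets_by_gen: dict[int, set]
) -> pd.DataFrame:
    """Per consecutive time-point pair (t, t_next): the fraction of time-t
    candidate SNPs whose rising allele reaches frequency 1 in at least one
    replicate at t_next (with positive depth), i.e. leaves the
    segregating-in-all universe.  Needs polarized frequencies.
    """
    f = ct.frequencies()
    ids = ct.snp_ids()
    id_index = pd.Series(np.arange(ct.n_snps), index=ids)
    tps = list(ct.timepoints)
    gens = sorted(g for g in sets_by_gen if g in tps)
    rows = []
    for t, t_next in zip(gens[:-1], gens[1:]):
        members = sets_by_gen[t]
        if not members:
            rows.append(
                {"t": t, "t_next": t_next, "ratio": 0.0, "n_candidates": 0}
            )
            continue
        idx = id_index.reindex(sorted(members)).dropna().to_numpy(dtype=int)
        ti = tps.index(t_next)
        fixed = (
            (f[idx, :, ti] == 1.0) & (ct.depth[idx, :, ti] > 0)
        ).any(axis=1)
        rows.append(
            {
                "t": t,
                "t_next": t_next,
                "ratio": float(fixed.mean()),
                "n_candidates": len(idx),
            }
        )
    return pd.DataFrame(rows)
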