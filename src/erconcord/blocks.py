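"""Haplotype-block discovery-rate (HADR) analysis and EDHA detection.

A haplotype block is a set of linked candidate SNPs rising together
(assignments are consumed as input — from the deposited table for real
data, or from ``simulate.make_blocks`` for synthetic runs).  Per block and
generation, the *haplotype block discovery rate* is the fraction of its
member SNPs re-detected as candidates at that generation.  Blocks whose
HADR trajectories cluster with elevated values already at generation 20
are *early-detected haplotype blocks* (EDHAs); clustering is k-means with
k chosen by the Tibshirani gap statistic, with hierarchical clustering and
a PCA projection available as concordant diagnostics.

Per-block features — span, median starting allele frequency, mean
recombination rate, selection coefficients s20 and s60 (logit-linear
trajectory fits averaged over replicates that actually respond), their
ratio r_s, and rising-replicate counts — are contrasted between EDHAs and
the rest with two-sided Mann-Whitney tests, BH-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .candidates import CandidateSet
from .sync_io import CountTensor


# ---------------------------------------------------------------------------
# HADR


def filter_blocks(
    members: dict[str, np.ndarray],
    ct: CountTensor,
    candidates_final: CandidateSet,
    min_recovery: float = 0.9,
) -> dict[str, np.ndarray]:
    """Keep blocks with >= ``min_recovery`` of members among the final-
    generation candidates (strict: recovery just below the floor drops
    the block)."""
    ids = ct.snp_ids()
    cand = candidates_final.as_set()
    out = {}
    for bid, idx in members.items():
        if len(idx) == 0:
            continue
        rec = np.mean([i in cand for i in ids[idx]])
        if rec >= min_recovery:
            out[bid] = idx
    return out


def hadr(
    member_idx: np.ndarray, ct: CountTensor, candidates_t: CandidateSet
) -> float:
    """Fraction of a block's member SNPs found in ``candidates_t``."""
    if len(member_idx) == 0:
        return 0.0
    cand = candidates_t.as_set()
    ids = ct.snp_ids()[member_idx]
    return float(np.mean([i in cand for i in ids]))


def hadr_matrix(
    members: dict[str, np.ndarray],
    ct: CountTensor,
    candidates_by_gen: dict[int, CandidateSet],
) -> pd.DataFrame:
    """Blocks x generations HADR matrix (rows ordered by block id)."""
    gens = sorted(candidates_by_gen)
    data = {
        g: [hadr(members[b], ct, candidates_by_gen[g]) for b in sorted(members)]
        for g in gens
    }
    return pd.DataFrame(data, index=sorted(members))


# ---------------------------------------------------------------------------
# Gap statistic + EDHA clustering


def _pooled_within_dispersion(x: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for lab in np.unique(labels):
        pts = x[labels == lab]
        if len(pts) > 1:
            w += ((pts - pts.mean(axis=0)) ** 2).sum()
    return max(w, 1e-12)


def gap_statistic(
    x: np.ndarray,
    k_max: int = 10,
    n_ref: int = 50,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Tibshirani gap statistic over k = 1..k_max.

    Reference sets are uniform over the feature-wise bounding box of the
    data; k is chosen by the first-standard-error rule (smallest k with
    gap(k) >= gap(k+1) - se(k+1)).  Returns (k, per-k table).
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(axis=0), x.max(axis=0)
    ks = np.arange(1, min(k_max, len(x)) + 1)

    def log_wk(data: np.ndarray, k: int, rs: int) -> float:
        if k == 1:
            labels = np.zeros(len(data), dtype=int)
        else:
            labels = KMeans(
                n_clusters=k, n_init=10, random_state=rs
            ).fit_predict(data)
        return float(np.log(_pooled_within_dispersion(data, labels)))

    rows = []
    for k in ks:
        obs = log_wk(x, k, int(rng.integers(2**31 - 1)))
        refs = np.array(
            [
                log_wk(
                    rng.uniform(lo, hi, size=x.shape),
                    k,
                    int(rng.integers(2**31 - 1)),
                )
                for _ in range(n_ref)
            ]
        )
        gap = refs.mean() - obs
        se = refs.std(ddof=1) * np.sqrt(1 + 1 / n_ref)
        rows.append({"k": int(k), "gap": gap, "se": se})
    tab = pd.DataFrame(rows)
    k_hat = int(tab["k"].iloc[-1])
    for i in range(len(tab) - 1):
        if tab["gap"][i] >= tab["gap"][i + 1] - tab["se"][i + 1]:
            k_hat = int(tab["k"][i])
            break
    return k_hat, tab


def find_edha(
    hadr_mat: pd.DataFrame,
    k: int | None = None,
    early_generation: int = 20,
    k_max: int = 10,
    n_ref: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Flag early-detected blocks by clustering HADR trajectories.

    k-means on the HADR row-vectors; ``k=None`` selects k by the gap
    statistic.  The EDHA cluster is the one with maximal mean HADR at
    ``early_generation``; a single cluster (k = 1, e.g. all trajectories
    identical) yields no EDHAs.  Output is deterministic given the seed
    and invariant to row order.  Columns: cluster, edha, plus diagnostics
    (hierarchical cluster at the same k, first two principal components).
    """
    x = hadr_mat.to_numpy(dtype=float)
    order = np.argsort(hadr_mat.index.to_numpy())
    x_sorted = x[order]
    if k is None:
        k, _ = gap_statistic(x_sorted, k_max=k_max, n_ref=n_ref, seed=seed)
    if k <= 1 or np.allclose(x_sorted.std(axis=0), 0):
        out = pd.DataFrame(
            {
                "cluster": np.zeros(len(x), dtype=int),
                "edha": np.zeros(len(x), dtype=bool),
            },
            index=hadr_mat.index,
        )
        out["hier_cluster"] = 0
        out["pc1"] = 0.0
        out["pc2"] = 0.0
        return out
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels_sorted = km.fit_predict(x_sorted)
    labels = np.empty(len(x), dtype=int)
    labels[order] = labels_sorted
    col = hadr_mat.columns.get_indexer([early_generation])[0]
    if col < 0:
        raise KeyError(f"generation {early_generation} not in HADR matrix")
    means = [
        x[labels == lab, col].mean() for lab in range(k)
    ]
    edha_lab = int(np.argmax(means))

    hier = fcluster(
        linkage(x_sorted, method="ward"), t=k, criterion="maxclust"
    )
    hier_full = np.empty(len(x), dtype=int)
    hier_full[order] = hier
    n_pc = min(2, x.shape[1], max(1, len(x) - 1))
    pcs_sorted = PCA(n_components=n_pc, random_state=seed).fit_transform(
        x_sorted
    )
    pcs = np.zeros((len(x), 2))
    pcs[order, :n_pc] = pcs_sorted
    return pd.DataFrame(
        {
            "cluster": labels,
            "edha": labels == edha_lab,
            "hier_cluster": hier_full,
            "pc1": pcs[:, 0],
            "pc2": pcs[:, 1],
        },
        index=hadr_mat.index,
    )


# ---------------------------------------------------------------------------
# Selection coefficients and block features


def estimate_s(
    traj: np.ndarray,
    times: np.ndarray,
    afc_threshold: float = 0.10,
) -> float:
    """Block selection coefficient from replicate mean-frequency
    trajectories.

    ``traj``: (R, T) rising-allele frequencies (member-SNP means) at
    ``times``.  Replicates qualify when their frequency change over the
    span is >= ``afc_threshold`` (non-responding replicates would bias s
    downward).  Per qualifying replicate: least-squares fit of logit(p)
    against generation using interior points only (p exactly 0 or 1 is
    dropped), s_hat = exp(slope) - 1 — exact for the deterministic
    multiplicative-codominant recursion.  Returns the mean over qualifying
    replicates, or NaN when none qualify.
    """
    traj = np.atleast_2d(np.asarray(traj, dtype=float))
    times = np.asarray(times, dtype=float)
    out = []
    for rep in traj:
        if rep[-1] - rep[0] < afc_threshold:
            continue
        keep = (rep > 0) & (rep < 1) & np.isfinite(rep)
        if keep.sum() < 2:
            continue
        y = np.log(rep[keep] / (1 - rep[keep]))
        slope = np.polyfit(times[keep], y, 1)[0]
        out.append(np.expm1(slope))
    return float(np.mean(out)) if out else float("nan")


def block_trajectories(
    members: dict[str, np.ndarray], ct: CountTensor
) -> dict[str, np.ndarray]:
    """Per block: (R, T) mean member-SNP rising-allele frequency."""
    f = ct.frequencies()
    return {
        bid: np.nanmean(f[idx], axis=0) for bid, idx in members.items()
    }


def rising_replicates(
    traj: np.ndarray, times: np.ndarray, gen: int, threshold: float = 0.10
) -> int:
    """Replicates whose mean member-SNP frequency rises by >= threshold
    from generation 0 to ``gen``."""
    times = list(np.asarray(times))
    ti = times.index(gen)
    afc = traj[:, ti] - traj[:, 0]
    return int(np.sum(afc >= threshold))


def mean_recomb_rate(
    chrom: str, start: int, end: int, recmap: pd.DataFrame | None
) -> float:
    """Mean map rate (cM/Mb) over [start, end], weighted by overlap length.

    ``recmap`` columns: chrom, window_start, window_end, rate.
    """
    if recmap is None:
        return float("nan")
    m = recmap[recmap["chrom"].astype(str) == str(chrom)]
    ov_start = np.maximum(m["window_start"].to_numpy(), start)
    ov_end = np.minimum(m["window_end"].to_numpy(), end)
    w = np.maximum(0, ov_end - ov_start).astype(float)
    if w.sum() == 0:
        return float("nan")
    return float(np.average(m["rate"].to_numpy(), weights=w))


FEATURES = (
    "length_bp",
    "median_start_af",
    "recomb_rate",
    "s20",
    "s60",
    "r_s",
    "rising20",
    "rising60",
)


def block_table(
    members: dict[str, np.ndarray],
    ct: CountTensor,
    candidates_by_gen: dict[int, CandidateSet],
    recmap: pd.DataFrame | None = None,
    early_generation: int = 20,
    final_generation: int = 60,
    afc_threshold: float = 0.10,
    rising_thresholds=(0.05, 0.10, 0.15, 0.20),
    edha_flags: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the per-block feature table.

    s20 fits the trajectory over generations [0, early_generation]
    (all sampled points in the span), s60 over [0, final_generation];
    r_s = s20/s60 is defined only for s60 != 0.  Rising-replicate counts
    are reported at every threshold in ``rising_thresholds``.
    """
    f = ct.frequencies()
    times = np.asarray(ct.timepoints)
    early_span = times <= early_generation
    rows = []
    for bid in sorted(members):
        idx = members[bid]
        traj = np.nanmean(f[idx], axis=0)  # (R, T)
        pos = ct.pos[idx]
        s20 = estimate_s(
            traj[:, early_span], times[early_span], afc_threshold
        )
        s60 = estimate_s(traj, times, afc_threshold)
        row = {
            "block_id": bid,
            "n_snps": len(idx),
            "chrom": ct.chrom[idx[0]],
            "length_bp": int(pos.max() - pos.min()),
            "median_start_af": float(np.nanmedian(f[idx, :, 0])),
            "recomb_rate": mean_recomb_rate(
                ct.chrom[idx[0]], int(pos.min()), int(pos.max()), recmap
            ),
            "s20": s20,
            "s60": s60,
            "r_s": s20 / s60 if s60 and np.isfinite(s60) and s60 != 0 else np.nan,
        }
        for thr in rising_thresholds:
            row[f"rising{int(round(thr * 100))}pct_g{early_generation}"] = (
                rising_replicates(traj, times, early_generation, thr)
            )
            row[f"rising{int(round(thr * 100))}pct_g{final_generation}"] = (
                rising_replicates(traj, times, final_generation, thr)
            )
        row["rising20"] = row[f"rising10pct_g{early_generation}"]
        row["rising60"] = row[f"rising10pct_g{final_generation}"]
        for g, cs in candidates_by_gen.items():
            row[f"hadr_g{g}"] = hadr(idx, ct, cs)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("block_id")
    if edha_flags is not None:
        df["edha"] = edha_flags.reindex(df.index).fillna(False).astype(bool)
    return df


def compare_features(
    blocks: pd.DataFrame, features=FEATURES, alpha: float = 0.05
) -> pd.DataFrame:
    """EDHA vs non-EDHA two-sided Mann-Whitney test per feature, BH-
    adjusted across the feature family.  Identical groups give p = 1."""
    if "edha" not in blocks.columns:
        raise ValueError("blocks table lacks an 'edha' column")
    g1 = blocks[blocks["edha"]]
    g0 = blocks[~blocks["edha"]]
    rows = []
    for feat in features:
        x = g1[feat].dropna().to_numpy()
        y = g0[feat].dropna().to_numpy()
        if len(x) == 0 or len(y) == 0 or (
            np.all(x == x[0]) and np.all(y == x[0])
        ):
            p = 1.0
            u = np.nan
        else:
            u, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append(
            {
                "feature": feat,
                "n_edha": len(x),
                "n_other": len(y),
                "median_edha": float(np.median(x)) if len(x) else np.nan,
                "median_other": float(np.median(y)) if len(y) else np.nan,
                "U": u,
                "p_raw": p,
            }
        )
    df = pd.DataFrame(rows)
    rej, p_adj, _, _ = multipletests(
        df["p_raw"].to_numpy(), alpha=alpha, method="fdr_bh"
    )
    df["p_adj"] = p_adj
    df["significant"] = rej
    return df
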