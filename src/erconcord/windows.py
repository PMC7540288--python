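"""Window-level enrichment scan and rank-overlap curves.

Chromosomes X, 2 and 3 are tiled with non-overlapping windows of a fixed
number of SNPs (default 5,000) that segregate in all generations and
replicates; SNP-count windows absorb variation in SNP density.  A window
is *enriched* at a time point when it holds at least as many candidate
SNPs as the 99th percentile of a random-placement null in which the same
number of SNPs is repeatedly sampled, without replacement, from all
windowed SNPs.

Within a candidate window, agreement of SNP *ranking* between two time
points is summarised by a ROC-like curve: rank candidates by p-value
(rank 1 most significant, ties broken by genomic position) and report
|top-r at t1 ∩ top-r at t2| / r for r = 1..n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .candidates import CandidateSet
from .sync_io import CountTensor

MAIN_CHROMS = ("X", "2", "2L", "2R", "3", "3L", "3R")


@dataclass
class WindowTable:
    """Non-overlapping SNP-count windows over the segregating universe."""

    table: pd.DataFrame  # window_id, chrom, start_pos, end_pos, n_snps
    snp_window: pd.Series  # snp_id -> window_id for every windowed SNP

    @property
    def n_windows(self) -> int:
        return len(self.table)

    def universe(self) -> np.ndarray:
        return self.snp_window.index.to_numpy()


def build_windows(
    ct: CountTensor,
    mask: np.ndarray,
    window_snps: int = 5000,
    chroms=MAIN_CHROMS,
) -> WindowTable:
    """Tile each main chromosome with consecutive runs of ``window_snps``
    mask-true SNPs (genome order); the trailing remainder is dropped.
    """
    rows = []
    snp_ids_all: list[np.ndarray] = []
    wid_all: list[np.ndarray] = []
    ids = ct.snp_ids()
    for chrom in pd.unique(ct.chrom):
        if str(chrom) not in chroms:
            continue
        on = np.where((ct.chrom == chrom) & mask)[0]
        on = on[np.argsort(ct.pos[on], kind="stable")]
        n_win = len(on) // window_snps
        for w in range(n_win):
            sl = on[w * window_snps : (w + 1) * window_snps]
            wid = f"{chrom}:w{w}"
            rows.append(
                {
                    "window_id": wid,
                    "chrom": chrom,
                    "start_pos": int(ct.pos[sl[0]]),
                    "end_pos": int(ct.pos[sl[-1]]),
                    "n_snps": len(sl),
                }
            )
            snp_ids_all.append(ids[sl])
            wid_all.append(np.full(len(sl), wid, dtype=object))
    if rows:
        snp_window = pd.Series(
            np.concatenate(wid_all), index=np.concatenate(snp_ids_all)
        )
    else:
        snp_window = pd.Series(dtype=object)
    return WindowTable(table=pd.DataFrame(rows), snp_window=snp_window)


def count_candidates(wt: WindowTable, cs: CandidateSet) -> np.ndarray:
    """Observed candidate-SNP count per window (windowed members only)."""
    members = wt.snp_window.reindex(cs.snp_ids).dropna()
    counts = members.value_counts()
    return (
        counts.reindex(wt.table["window_id"]).fillna(0).to_numpy(dtype=int)
    )


def enrichment_null(
    wt: WindowTable,
    cs: CandidateSet,
    iterations: int = 1000,
    percentile: float = 99.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Random-placement enrichment test for one time point.

    Each iteration drops the observed number of windowed candidates
    uniformly without replacement onto all windowed SNPs and counts hits
    per window.  The per-window threshold is the ceiling-index order
    statistic of the null counts at ``percentile``; enriched means
    observed >= threshold.  Returns the window table with columns
    candidate_count, null_threshold, enriched.
    """
    rng = np.random.default_rng(seed)
    observed = count_candidates(wt, cs)
    m = int(observed.sum())
    sizes = wt.table["n_snps"].to_numpy()
    W = wt.n_windows
    out = wt.table.copy()
    out["timepoint"] = cs.timepoint
    out["candidate_count"] = observed
    if W == 0 or m == 0:
        out["null_threshold"] = np.inf if m == 0 else 0
        out["enriched"] = False
        if m > 0:
            out["enriched"] = observed >= out["null_threshold"]
        return out
    null_counts = np.empty((iterations, W), dtype=np.int64)
    for i in range(iterations):
        null_counts[i] = rng.multivariate_hypergeometric(sizes, m)
    k = int(np.ceil(percentile / 100.0 * iterations)) - 1
    thr = np.sort(null_counts, axis=0)[k]
    out["null_threshold"] = thr
    out["enriched"] = observed >= thr
    return out


def candidate_windows(enrich: pd.DataFrame) -> set:
    """Window-id set of enriched windows from an enrichment table."""
    return set(enrich.loc[enrich["enriched"], "window_id"].tolist())


# ---------------------------------------------------------------------------
# Rank overlap


def _ranked_ids(snp_ids: np.ndarray, pvals: np.ndarray) -> list:
    """Ids sorted by (p, chrom, pos); rank 1 = most significant."""
    def keyfun(i):
        c, p = snp_ids[i].split(":")
        return (pvals[i], c, int(p))

    order = sorted(range(len(snp_ids)), key=keyfun)
    return [snp_ids[i] for i in order]


def rank_overlap(
    ids_t1: np.ndarray,
    pvals_t1: np.ndarray,
    ids_t2: np.ndarray,
    pvals_t2: np.ndarray,
) -> pd.DataFrame:
    """ROC-like rank-overlap curve between two time points in one window.

    Returns a frame with columns r, overlap, reference where ``overlap`` is
    |top-r(t1) ∩ top-r(t2)|/r and ``reference`` is the curve expected if
    every t2 variant were recapitulated at t1: min(r, n_t1)/r.  Raises on
    an empty candidate list at either time point (callers skip those).
    """
    if len(ids_t1) == 0 or len(ids_t2) == 0:
        raise ValueError("rank overlap undefined for empty candidate lists")
    r1 = _ranked_ids(np.asarray(ids_t1), np.asarray(pvals_t1))
    r2 = _ranked_ids(np.asarray(ids_t2), np.asarray(pvals_t2))
    n = max(len(r1), len(r2))
    seen1: set = set()
    seen2: set = set()
    inter = 0
    rows = []
    for r in range(1, n + 1):
        if r <= len(r1):
            x = r1[r - 1]
            if x in seen2:
                inter += 1
            seen1.add(x)
        if r <= len(r2):
            x = r2[r - 1]
            if x in seen1:
                inter += 1
            seen2.add(x)
        rows.append(
            {
                "r": r,
                "overlap": inter / r,
                "reference": min(r, len(r1)) / r,
            }
        )
    return pd.DataFrame(rows)


def window_rank_overlap(
    wt: WindowTable,
    cs_early: CandidateSet,
    cs_late: CandidateSet,
    windows: set | None = None,
) -> dict[str, pd.DataFrame]:
    """Rank-overlap curves per window (late time point as reference).

    ``windows`` restricts to a window-id subset (e.g. candidate windows at
    the late time point); windows lacking candidates at either time point
    are skipped.
    """
    out: dict[str, pd.DataFrame] = {}
    w_early = wt.snp_window.reindex(cs_early.snp_ids).dropna()
    w_late = wt.snp_window.reindex(cs_late.snp_ids).dropna()
    p_early = pd.Series(cs_early.pvalues, index=cs_early.snp_ids)
    p_late = pd.Series(cs_late.pvalues, index=cs_late.snp_ids)
    wids = windows if windows is not None else set(wt.table["window_id"])
    for wid in sorted(wids):
        ids1 = w_early.index[w_early == wid].to_numpy()
        ids2 = w_late.index[w_late == wid].to_numpy()
        if len(ids1) == 0 or len(ids2) == 0:
            continue
        out[wid] = rank_overlap(
            ids1, p_early[ids1].to_numpy(), ids2, p_late[ids2].to_numpy()
        )
    return out
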