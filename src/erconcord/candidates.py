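"""Candidate-SNP calling against a neutral-drift null.

Per time point t each SNP is scored on the allele-count contrast between
generation 0 and generation t:

* jointly across replicates with the Cochran-Mantel-Haenszel (CMH) test —
  replicates are strata, each contributing a 2x2 table of (rising/other
  allele) x (generation 0/t) raw read counts; classical 1-df chi-square,
  no continuity correction;
* per replicate with Fisher's exact test.

Neither test accounts for drift, so the significance threshold comes from
neutral Wright-Fisher simulations at the estimated effective size, run at
the empirical starting frequencies and read depths, scored with the same
tests.  Candidates are the SNPs whose p-value is below the largest cutoff
at which the estimated false discovery rate — the expected fraction of
neutral SNPs among calls — stays below q (default 5%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sync_io import CountTensor


# ---------------------------------------------------------------------------
# Tests


def cmh_test(tables: np.ndarray) -> tuple[float, float]:
    """Cochran-Mantel-Haenszel chi-square for K stratified 2x2 tables.

    Parameters
    ----------
    tables : (K, 2, 2) array; rows = allele, columns = generation.

    Returns (statistic, two-sided p).  Strata with a zero margin are
    skipped; if every stratum is degenerate the result is (0, 1).
    """
    t = np.asarray(tables, dtype=float)
    if t.ndim == 2:
        t = t[None]
    a = t[:, 0, 0]
    r1 = t[:, 0, :].sum(axis=1)
    r2 = t[:, 1, :].sum(axis=1)
    c1 = t[:, :, 0].sum(axis=1)
    c2 = t[:, :, 1].sum(axis=1)
    n = r1 + r2
    ok = (r1 > 0) & (r2 > 0) & (c1 > 0) & (c2 > 0) & (n > 1)
    if not ok.any():
        return 0.0, 1.0
    e = r1[ok] * c1[ok] / n[ok]
    v = r1[ok] * r2[ok] * c1[ok] * c2[ok] / (n[ok] ** 2 * (n[ok] - 1))
    num = (a[ok] - e).sum() ** 2
    den = v.sum()
    if den <= 0:
        return 0.0, 1.0
    stat = num / den
    return float(stat), float(stats.chi2.sf(stat, df=1))


def cmh_test_counts(
    a0: np.ndarray, d0: np.ndarray, at: np.ndarray, dt: np.ndarray
) -> np.ndarray:
    """Vectorized CMH p-values for S SNPs x K replicate strata.

    ``a0``/``at``: rising-allele counts at generations 0/t, shape (S, K);
    ``d0``/``dt``: depths.  Returns p-values of length S.  Strata with a
    zero margin drop out of both numerator and variance; SNPs with no
    usable stratum get p = 1.
    """
    a0 = np.asarray(a0, float)
    at = np.asarray(at, float)
    d0 = np.asarray(d0, float)
    dt = np.asarray(dt, float)
    r1 = a0 + at  # rising-allele row margin
    r2 = (d0 - a0) + (dt - at)
    c1, c2 = d0, dt
    n = c1 + c2
    ok = (r1 > 0) & (r2 > 0) & (c1 > 0) & (c2 > 0) & (n > 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(ok, r1 * c1 / n, 0.0)
        v = np.where(ok, r1 * r2 * c1 * c2 / (n**2 * (n - 1)), 0.0)
    num = (np.where(ok, a0 - e, 0.0)).sum(axis=1) ** 2
    den = v.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(den > 0, num / den, 0.0)
    return stats.chi2.sf(stat, df=1)


def fisher_test(table) -> float:
    """Two-sided Fisher's exact p for one 2x2 table."""
    _, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(p)


def fisher_test_counts(
    a0: np.ndarray, d0: np.ndarray, at: np.ndarray, dt: np.ndarray
) -> np.ndarray:
    """Vectorized two-sided Fisher p-values for S SNPs (one replicate).

    Two-sided by the standard "probabilities <= that of the observed
    table" rule, evaluated through the hypergeometric pmf.
    """
    a0 = np.asarray(a0, int)
    at = np.asarray(at, int)
    d0 = np.asarray(d0, int)
    dt = np.asarray(dt, int)
    out = np.ones(len(a0))
    for i in range(len(a0)):
        r1 = a0[i] + at[i]
        n = d0[i] + dt[i]
        if r1 == 0 or r1 == n or d0[i] == 0 or dt[i] == 0:
            continue
        kmin = max(0, r1 - dt[i])
        kmax = min(r1, d0[i])
        support = np.arange(kmin, kmax + 1)
        pmf = stats.hypergeom.pmf(support, n, r1, d0[i])
        p_obs = pmf[a0[i] - kmin]
        out[i] = min(1.0, pmf[pmf <= p_obs * (1 + 1e-10)].sum())
    return out


# ---------------------------------------------------------------------------
# Neutral null and empirical FDR


def simulate_null_pvalues(
    f0: np.ndarray,
    depth0: np.ndarray,
    deptht: np.ndarray,
    ne: float,
    t: int,
    seed: int,
    test: str = "cmh",
) -> np.ndarray:
    """Null p-value ensemble from neutral drift + Pool-seq sampling.

    For each of S SNPs: per replicate, the true frequency starts at the
    empirical ``f0`` and drifts for ``t`` generations by binomial sampling
    of 2*Ne gene copies; reads are then drawn binomially at the empirical
    depths of both time points, and the same test as for the observed data
    is applied.

    ``f0``: (S,) empirical starting frequencies (pooled across replicates);
    ``depth0``/``deptht``: (S, K) empirical depths.  Returns (S,) p-values
    for "cmh" or (S, K) for "fisher".
    """
    rng = np.random.default_rng(seed)
    f0 = np.asarray(f0, dtype=float)
    depth0 = np.atleast_2d(np.asarray(depth0))
    deptht = np.atleast_2d(np.asarray(deptht))
    S, K = depth0.shape
    copies = max(2, int(round(2 * ne)))
    p = np.broadcast_to(f0[:, None], (S, K)).copy()
    for _ in range(t):
        p = rng.binomial(copies, p) / copies
    a0 = rng.binomial(depth0, f0[:, None])
    at = rng.binomial(deptht, p)
    if test == "cmh":
        return cmh_test_counts(a0, depth0, at, deptht)
    if test == "fisher":
        return np.column_stack(
            [
                fisher_test_counts(a0[:, k], depth0[:, k], at[:, k], deptht[:, k])
                for k in range(K)
            ]
        )
    raise ValueError(f"unknown test: {test}")


def fdr_threshold(
    observed_p: np.ndarray, null_p: np.ndarray, q: float = 0.05
) -> tuple[float, np.ndarray, float]:
    """Largest p-value cutoff with estimated FDR <= q.

    FDR_hat(c) = (#{null <= c} * |observed|/|null|) / #{observed <= c}.
    Returns (threshold, boolean candidate mask, achieved FDR_hat); the
    threshold is -inf (empty set) when no cutoff satisfies the bound.
    """
    obs = np.asarray(observed_p, dtype=float)
    nul = np.sort(np.asarray(null_p, dtype=float))
    scale = len(obs) / len(nul)
    order = np.argsort(obs, kind="stable")
    obs_sorted = obs[order]
    n_obs = np.arange(1, len(obs) + 1)
    n_null = np.searchsorted(nul, obs_sorted, side="right")
    fdr_hat = np.minimum((n_null * scale) / n_obs, 1.0)
    good = np.where(fdr_hat <= q)[0]
    if len(good) == 0:
        return -np.inf, np.zeros(len(obs), dtype=bool), np.nan
    cut_idx = good[-1]
    threshold = obs_sorted[cut_idx]
    mask = obs <= threshold
    return float(threshold), mask, float(fdr_hat[cut_idx])


@dataclass
class CandidateSet:
    """SNPs passing the neutral-simulation FDR threshold at one time point."""

    timepoint: int
    snp_ids: np.ndarray  # chrom:pos strings of members
    pvalues: np.ndarray  # matching member p-values
    threshold: float
    fdr: float
    test: str = "cmh"
    all_snp_ids: np.ndarray | None = None
    all_pvalues: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def as_set(self) -> set:
        return set(self.snp_ids.tolist())

    def __len__(self) -> int:
        return len(self.snp_ids)


def scan_timepoint(
    ct: CountTensor,
    t: int,
    ne: float,
    q: float = 0.05,
    seed: int = 0,
    n_sims: int = 1,
    snp_mask: np.ndarray | None = None,
) -> CandidateSet:
    """CMH candidate scan of one time point against its neutral null.

    ``ne`` is the cross-replicate averaged effective size for the span
    (0, t).  ``snp_mask`` restricts the tested universe (e.g. to SNPs
    segregating everywhere); SNPs fixed in all replicates at t are always
    excluded.  ``n_sims`` repeats of the matched null ensemble are merged
    before thresholding.
    """
    tp = list(ct.timepoints)
    ti = tp.index(t)
    f = ct.frequencies()
    if snp_mask is None:
        snp_mask = np.ones(ct.n_snps, dtype=bool)
    seg_t = ~(
        ((ct.depth[:, :, ti] == 0) | (f[:, :, ti] == 0) | (f[:, :, ti] == 1))
        .all(axis=1)
    )
    use = snp_mask & seg_t
    a0, d0 = ct.rising[use, :, 0], ct.depth[use, :, 0]
    at, dt = ct.rising[use, :, ti], ct.depth[use, :, ti]
    obs_p = cmh_test_counts(a0, d0, at, dt)

    with np.errstate(invalid="ignore"):
        f0 = np.where(
            d0.sum(axis=1) > 0, a0.sum(axis=1) / d0.sum(axis=1), 0.5
        )
    nulls = [
        simulate_null_pvalues(
            f0, d0, dt, ne=ne, t=t, seed=seed + 1000 * k, test="cmh"
        )
        for k in range(n_sims)
    ]
    null_p = np.concatenate(nulls)
    threshold, mask, fdr = fdr_threshold(obs_p, null_p, q=q)
    ids = ct.snp_ids()[use]
    return CandidateSet(
        timepoint=t,
        snp_ids=ids[mask],
        pvalues=obs_p[mask],
        threshold=threshold,
        fdr=fdr,
        test="cmh",
        all_snp_ids=ids,
        all_pvalues=obs_p,
        extra={"ne": ne, "q": q, "seed": seed, "n_tested": int(use.sum())},
    )
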