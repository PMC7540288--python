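"""Temporal effective-population-size estimation from Pool-seq data.

Implements a Waples-family moment estimator on the standardized squared
allele-frequency change

    F_c = (x - y)^2 / (z - x*y),   z = (x + y) / 2,

between generation 0 (frequency x) and generation t (frequency y), with a
two-stage sampling correction: Pool-seq observes frequencies through (i) a
pool of ``pool_size`` individuals drawn from the population and (ii) a
binomial read sample at the sequencing depth, so the expected contribution
of sampling noise to F_c at one time point is

    1/S_eff = 1/(2 n) + 1/D - 1/(2 n D)

for pool size n (diploids) and read depth D (sampling with replacement of
reads from 2n chromosomes; sampling plan II — the pool is returned to the
population, which itself is censused, so no 1/N term is added).  The drift
signal is F_c minus the noise expected at both time points, and

    Ne_hat = -t / (2 ln(1 - F_corrected)).

F_c and the noise terms are averaged over SNPs before the correction; the
ratio-of-sums variant (sum numerators / sum denominators) is available via
``average="ratio_of_sums"`` and is more robust for skewed frequency
spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sync_io import CountTensor


@dataclass
class NeEstimate:
    """Effective size for one replicate (or a cross-replicate average)."""

    ne: float
    scope: object  # replicate label or "averaged"
    chromosome_class: str  # "autosome" | "X"
    t: int
    f_corrected: float
    n_snps: int
    unbounded: bool = False


def _fc_terms(x, y, d0, dt, pool_size):
    """Per-SNP F_c numerator/denominator and two-stage noise terms.

    ``pool_size=None`` means the sequenced pool comprises the whole
    population (common in E&R, and the regime of the built-in simulator):
    the individual-sampling stage vanishes and only read noise remains.
    """
    z = (x + y) / 2.0
    num = (x - y) ** 2
    den = z - x * y
    if pool_size is None:
        noise0 = 1.0 / d0
        noiset = 1.0 / dt
    else:
        n2 = 2.0 * pool_size
        noise0 = 1.0 / n2 + 1.0 / d0 - 1.0 / (n2 * d0)
        noiset = 1.0 / n2 + 1.0 / dt - 1.0 / (n2 * dt)
    return num, den, noise0 + noiset


def estimate_ne(
    f0: np.ndarray,
    ft: np.ndarray,
    depth0: np.ndarray,
    deptht: np.ndarray,
    t: int,
    pool_size: int | None = None,
    scope="replicate",
    chromosome_class: str = "autosome",
    average: str = "ratio_of_sums",
) -> NeEstimate:
    """Moment estimate of Ne (diploids) from one replicate's two samples.

    Parameters
    ----------
    f0, ft : observed allele frequencies at generations 0 and t (any
        consistent polarization; the estimator is invariant to allele
        relabeling since both numerator and denominator are symmetric
        under (x, y) -> (1-x, 1-y)).
    depth0, deptht : read depths per SNP at the two time points.
    pool_size : number of diploid individuals sequenced per pool.
    average : "per_snp" (mean of per-SNP F_c ratios) or "ratio_of_sums".

    Returns an :class:`NeEstimate`; when the corrected F is <= 0 the drift
    signal is below sampling noise and the estimate is flagged unbounded.
    """
    f0 = np.asarray(f0, dtype=float)
    ft = np.asarray(ft, dtype=float)
    d0 = np.asarray(depth0, dtype=float)
    dt = np.asarray(deptht, dtype=float)
    ok = (d0 > 0) & (dt > 0) & np.isfinite(f0) & np.isfinite(ft)
    # sites fixed at both time points carry no information
    z = (f0 + ft) / 2.0
    ok &= (z > 0) & (z < 1)
    num, den, noise = _fc_terms(f0[ok], ft[ok], d0[ok], dt[ok], pool_size)
    n_snps = int(ok.sum())
    if n_snps == 0:
        return NeEstimate(
            np.nan, scope, chromosome_class, t, np.nan, 0, unbounded=True
        )
    if average == "ratio_of_sums":
        f_c = num.sum() / den.sum()
        f_corr = f_c - noise.mean()
    elif average == "per_snp":
        good = den > 0
        f_c = np.mean(num[good] / den[good])
        f_corr = f_c - noise[good].mean()
    else:
        raise ValueError(f"unknown averaging rule: {average}")
    if f_corr <= 0 or f_corr >= 1:
        return NeEstimate(
            np.nan, scope, chromosome_class, t, float(f_corr), n_snps, True
        )
    ne = -t / (2.0 * np.log(1.0 - f_corr))
    return NeEstimate(
        float(ne), scope, chromosome_class, t, float(f_corr), n_snps, False
    )


X_CHROMS = {"X"}


def estimate_ne_tensor(
    ct: CountTensor,
    t: int,
    pool_size: int | None = None,
    average: str = "ratio_of_sums",
) -> list[NeEstimate]:
    """Per-replicate Ne between generation 0 and generation ``t``.

    Autosomes and the X chromosome are estimated separately (the X has
    three copies per two individuals, so its drift and pool-sampling
    scales differ; pool_size is scaled by 3/4 for the X class).
    """
    tp = list(ct.timepoints)
    if t not in tp:
        raise ValueError(f"generation {t} not sampled")
    ti = tp.index(t)
    f = ct.frequencies()
    is_x = np.isin(ct.chrom, list(X_CHROMS))
    out: list[NeEstimate] = []
    x_pool = (
        None if pool_size is None else max(1, int(round(0.75 * pool_size)))
    )
    for cls, snp_mask, psize in (
        ("autosome", ~is_x, pool_size),
        ("X", is_x, x_pool),
    ):
        if not snp_mask.any():
            continue
        for ri, rep in enumerate(ct.replicates):
            out.append(
                estimate_ne(
                    f[snp_mask, ri, 0],
                    f[snp_mask, ri, ti],
                    ct.depth[snp_mask, ri, 0],
                    ct.depth[snp_mask, ri, ti],
                    t=t,
                    pool_size=psize,
                    scope=rep,
                    chromosome_class=cls,
                    average=average,
                )
            )
    return out


def average_ne(estimates: list[NeEstimate]) -> dict[str, NeEstimate]:
    """Arithmetic mean of bounded per-replicate estimates, per chromosome
    class.  Used for the cross-replicate (CMH) neutral null; per-replicate
    estimates feed the per-replicate (Fisher) nulls."""
    out: dict[str, NeEstimate] = {}
    for cls in sorted({e.chromosome_class for e in estimates}):
        vals = [
            e for e in estimates if e.chromosome_class == cls and not e.unbounded
        ]
        if not vals:
            continue
        out[cls] = NeEstimate(
            ne=float(np.mean([e.ne for e in vals])),
            scope="averaged",
            chromosome_class=cls,
            t=vals[0].t,
            f_corrected=float(np.mean([e.f_corrected for e in vals])),
            n_snps=int(np.mean([e.n_snps for e in vals])),
        )
    return out
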