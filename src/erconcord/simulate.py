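"""Synthetic Evolve-and-Resequence experiments.

Forward Wright-Fisher simulation of replicated laboratory populations with
Pool-seq read sampling, in three modes:

``unlinked``
    Each locus evolves independently: a deterministic codominant selection
    update followed by binomial drift at the census size.  Used for the
    winner's-curse experiment (many loci, identical starting frequency and
    selection coefficient) and for neutral calibration runs.
``linked``
    Diploid individuals carry haplotype pairs drawn from a finite founder
    pool; selection targets sit inside designated regions, gametes recombine
    according to a rate map, and every polymorphic site's frequency is
    recorded, so linked neutral hitchhikers are represented.
``neutral``
    Unlinked with all selection coefficients zero.

Selection is multiplicative codominant: each copy of the rising allele
multiplies fitness by ``1+s`` (genotype fitnesses ``(1+s)^2, 1+s, 1``), so
the deterministic trajectory is exactly log-linear on the logit scale with
slope ``ln(1+s)`` per generation.  Fitness combines multiplicatively
across target loci.
Pool-seq sampling draws a Poisson read depth per site x replicate x
timepoint and a binomial allele count at the true frequency.

Defaults mirror a hot-adapted *Drosophila simulans* study design:
10 replicates, census 1,000, generations 0-60 sampled every 10th,
founder pool of 189 haplotypes, selected sites starting at frequency 0.10
with s = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .sync_io import CountTensor

DEFAULT_GENERATIONS = (0, 10, 20, 30, 40, 50, 60)


@dataclass
class SimConfig:
    """Parameters of a synthetic E&R experiment.

    ``depth_lambda`` is the mean Pool-seq read depth; it may be a scalar or
    an (R, T) array for per-replicate/timepoint means.  ``p0`` is the
    starting frequency of selected loci; neutral loci in unlinked mode draw
    their starting frequency uniformly from ``neutral_p0_range`` unless
    ``p0_array`` pins them.  ``x_linked`` scales the number of gene copies
    to 1.5 N (three X chromosomes per two individuals).
    """

    mode: Literal["linked", "unlinked", "neutral"] = "unlinked"
    n_replicates: int = 10
    census_n: int = 1000
    generations: tuple[int, ...] = DEFAULT_GENERATIONS
    n_loci: int = 100_000
    p0: float = 0.10
    s: float = 0.05
    h: float = 0.5
    depth_lambda: float = 80.0
    n_founder_haplotypes: int = 189
    founder_ne: int = 1000
    genome_length: int = 20_000_000
    chrom: str = "2"
    recomb_rate_cm_mb: float = 2.0
    n_targets: int = 99
    neutral_p0_range: tuple[float, float] = (0.05, 0.95)
    p0_array: np.ndarray | None = None
    s_array: np.ndarray | None = None
    x_linked: bool = False
    effective_n: int | None = None  # drift size override; census by default
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.p0 < 1):
            raise ValueError("p0 must lie in (0, 1)")
        if self.census_n < 2:
            raise ValueError("census_n must be >= 2")
        if np.any(np.asarray(self.depth_lambda) <= 0):
            raise ValueError("depth_lambda must be > 0")
        if self.s <= -1:
            raise ValueError("s must exceed -1")
        gens = np.asarray(self.generations)
        if gens[0] != 0 or (np.diff(gens) <= 0).any():
            raise ValueError("generations must increase strictly from 0")

    @property
    def gene_copies(self) -> int:
        n = self.effective_n if self.effective_n is not None else self.census_n
        return int(round(1.5 * n)) if self.x_linked else 2 * n


@dataclass
class TruthTable:
    """True per-locus state of a simulated experiment.

    ``freq`` has shape (L, R, T): true rising-allele frequency of locus
    *l* in replicate *r* at sampled generation ``generations[t]``.
    """

    chrom: np.ndarray
    pos: np.ndarray
    is_target: np.ndarray
    s: np.ndarray
    p0: np.ndarray
    freq: np.ndarray
    generations: np.ndarray
    block_of_target: np.ndarray | None = None  # region id per target locus

    @property
    def n_loci(self) -> int:
        return self.freq.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Flat TSV-ready view: one row per locus, mean-replicate trajectory."""
        df = pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "is_target": self.is_target.astype(int),
                "s": self.s,
                "p0": self.p0,
            }
        )
        mean_traj = self.freq.mean(axis=1)
        for j, g in enumerate(self.generations):
            df[f"freq_gen{g}"] = mean_traj[:, j]
        return df


# ---------------------------------------------------------------------------
# Selection / drift primitives


def per_copy_s(s_homozygous: float) -> float:
    """Translate a homozygote-scale selection coefficient to this
    simulator's per-copy scale.

    Literature estimates for E&R sweeps usually state s on the homozygote
    with codominant (h = 0.5) dominance.  The simulator's multiplicative
    parametrization applies ``1 + s`` per allele copy, so a homozygote
    carries ``(1 + s)^2``; matching homozygote fitness ``1 + S`` gives
    ``s = sqrt(1 + S) - 1`` (~S/2 for small S).
    """
    return float(np.sqrt(1.0 + s_homozygous) - 1.0)


def selection_update(p: np.ndarray, s: np.ndarray) -> np.ndarray:
    """One deterministic generation of multiplicative codominant selection.

    Each copy of the rising allele multiplies fitness by (1+s): genotype
    fitnesses ((1+s)^2, 1+s, 1).  The recursion is genic,
    p' = p(1+s) / (1 + p s), hence exactly log-linear on the logit scale
    with per-generation increment ln(1+s) -- the property the trajectory-
    based selection-coefficient estimator inverts.
    """
    return p * (1 + s) / (1 + p * s)


def wf_unlinked(cfg: SimConfig, drift: bool = True) -> TruthTable:
    """Simulate independent loci under selection + drift in R replicates.

    Selected loci (``n_targets`` of them, or all loci when a scalar design
    is wanted -- set ``n_targets >= n_loci``) start at ``p0`` with
    coefficient ``s``; the remainder are neutral with uniform starting
    frequencies.  ``p0_array``/``s_array`` override per-locus values.
    Drift samples ``gene_copies`` binomially each generation; ``drift=False``
    runs the deterministic recursion only.
    """
    cfg.validate()
    if cfg.mode not in ("unlinked", "neutral"):
        raise ValueError("wf_unlinked requires mode 'unlinked' or 'neutral'")
    rng = np.random.default_rng(cfg.seed)
    L, R = cfg.n_loci, cfg.n_replicates
    gens = np.asarray(cfg.generations)
    T = len(gens)

    if cfg.p0_array is not None:
        p0 = np.asarray(cfg.p0_array, dtype=float)
        s_vec = (
            np.asarray(cfg.s_array, dtype=float)
            if cfg.s_array is not None
            else np.zeros(L)
        )
        is_target = s_vec != 0
    else:
        n_t = 0 if cfg.mode == "neutral" else min(cfg.n_targets, L)
        is_target = np.zeros(L, dtype=bool)
        is_target[:n_t] = True
        lo, hi = cfg.neutral_p0_range
        p0 = rng.uniform(lo, hi, size=L)
        p0[is_target] = cfg.p0
        s_vec = np.where(is_target, cfg.s, 0.0)

    ncopies = cfg.gene_copies
    p = np.broadcast_to(p0[:, None], (L, R)).copy()
    freq = np.empty((L, R, T))
    freq[:, :, 0] = p
    t_idx = 1
    for g in range(1, gens[-1] + 1):
        p = selection_update(p, s_vec[:, None])
        if drift:
            p = rng.binomial(ncopies, p) / ncopies
        if t_idx < T and g == gens[t_idx]:
            freq[:, :, t_idx] = p
            t_idx += 1

    pos = np.arange(1, L + 1, dtype=np.int64) * max(
        1, cfg.genome_length // max(L, 1)
    )
    return TruthTable(
        chrom=np.full(L, cfg.chrom, dtype=object),
        pos=pos,
        is_target=is_target,
        s=s_vec,
        p0=p0,
        freq=freq,
        generations=gens,
    )


# ---------------------------------------------------------------------------
# Linked mode


def founder_haplotypes(cfg: SimConfig, rng: np.random.Generator):
    """Build a founder haplotype pool with realistic linkage.

    Uses msprime (coalescent with recombination, mutation) to produce
    ``n_founder_haplotypes`` haplotypes over ``genome_length`` bp, then
    thins to at most ``n_loci`` segregating sites.  This synthetic pool
    stands in for an empirically phased founder panel.

    Returns (haplotypes uint8 (H, L), positions int64 (L,)).
    """
    import msprime

    bp_per_morgan = 1e8 / cfg.recomb_rate_cm_mb
    r = 1.0 / bp_per_morgan
    # overshoot: discrete-genome mutation stacking and the segregating
    # filter eat into the raw site count; surplus is subsampled away
    target_sites = int(cfg.n_loci * 2.6) + 50
    # Coalescent at founder-pool scale: a laboratory founder population
    # (a few hundred field-caught lines) carries long-range LD, emulated
    # by a modest coalescent Ne rather than the wild census size.
    ne = cfg.founder_ne
    # Watterson: E[S] = 4 Ne mu L_bp * a_{H-1}; solve mu for target_sites
    a_h = np.sum(1.0 / np.arange(1, cfg.n_founder_haplotypes))
    mu = target_sites / (4 * ne * cfg.genome_length * a_h)
    ts = msprime.sim_ancestry(
        samples=cfg.n_founder_haplotypes,
        ploidy=1,
        population_size=ne,
        sequence_length=cfg.genome_length,
        recombination_rate=r,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    ts = msprime.sim_mutations(
        ts,
        rate=mu,
        random_seed=int(rng.integers(1, 2**31 - 1)),
        model=msprime.BinaryMutationModel(),
    )
    haps = ts.genotype_matrix().T.astype(np.uint8)  # (H, sites)
    haps = np.minimum(haps, 1)
    pos = ts.tables.sites.position.astype(np.int64)
    # drop non-segregating and duplicate integer positions
    seg = (haps.sum(axis=0) > 0) & (haps.sum(axis=0) < haps.shape[0])
    keep = seg & np.r_[True, np.diff(pos) > 0]
    haps, pos = haps[:, keep], pos[keep]
    if haps.shape[1] > cfg.n_loci:
        sel = np.sort(
            rng.choice(haps.shape[1], size=cfg.n_loci, replace=False)
        )
        haps, pos = haps[:, sel], pos[sel]
    return haps, pos


def _choose_targets(
    haps: np.ndarray, pos: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Pick ``n_targets`` sites with founder frequency nearest p0, spread
    across the genome (one per equal-width bin where possible)."""
    f = haps.mean(axis=0)
    n_t = min(cfg.n_targets, len(pos))
    bins = np.linspace(pos[0], pos[-1] + 1, n_t + 1)
    chosen: list[int] = []
    for b in range(n_t):
        in_bin = np.where((pos >= bins[b]) & (pos < bins[b + 1]))[0]
        in_bin = in_bin[(f[in_bin] > 0.02) & (f[in_bin] < 0.98)]
        if len(in_bin) == 0:
            continue
        chosen.append(in_bin[np.argmin(np.abs(f[in_bin] - cfg.p0))])
    return np.array(sorted(set(chosen)), dtype=np.int64)


def _recombine(
    hap1: np.ndarray,
    hap2: np.ndarray,
    pos_morgans: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Form one gamete per parent by crossover between its two haplotypes.

    ``hap1``/``hap2``: (n, L) haplotypes of the chosen parents.  Crossover
    count per gamete ~ Poisson(total map length in Morgans), breakpoint
    positions uniform on the genetic map (no interference).
    """
    n, L = hap1.shape
    lo = pos_morgans[0]
    total = float(pos_morgans[-1] - lo)
    start = rng.integers(0, 2, size=n).astype(np.uint8)
    choice = np.repeat(start[:, None], L, axis=1)
    n_co = rng.poisson(total, size=n) if total > 0 else np.zeros(n, int)
    rows = np.where(n_co > 0)[0]
    if rows.size:
        flips = np.zeros((rows.size, L), dtype=np.int8)
        for k, i in enumerate(rows):
            cuts = np.searchsorted(
                pos_morgans, lo + rng.uniform(0, total, size=n_co[i])
            )
            cuts = cuts[cuts < L]
            np.add.at(flips[k], cuts, 1)
        parity = (
            start[rows, None] + np.cumsum(flips, axis=1, dtype=np.int32)
        ) % 2
        choice[rows] = parity.astype(np.uint8)
    return np.where(choice == 0, hap1, hap2)


def wf_linked(
    cfg: SimConfig,
    haplotypes: np.ndarray | None = None,
    positions: np.ndarray | None = None,
    recomb_map: pd.DataFrame | None = None,
    target_idx: np.ndarray | None = None,
) -> TruthTable:
    """Simulate replicated diploid populations with linkage and sweeps.

    Individuals are haplotype pairs over all polymorphic founder sites;
    each generation parents are sampled proportional to multiplicative
    fitness over target genotypes and gametes recombine per the rate map
    (constant ``recomb_rate_cm_mb`` unless ``recomb_map`` with columns
    chrom/window_start/window_end/rate is given).  Frequencies of *all*
    sites are recorded at the sampled generations.
    """
    cfg.validate()
    if cfg.mode != "linked":
        raise ValueError("wf_linked requires mode 'linked'")
    rng = np.random.default_rng(cfg.seed)
    if haplotypes is None:
        haplotypes, positions = founder_haplotypes(cfg, rng)
    haps = np.asarray(haplotypes, dtype=np.uint8)
    pos = np.asarray(positions, dtype=np.int64)
    H, L = haps.shape

    if target_idx is None:
        if cfg.mode == "linked" and cfg.n_targets > 0:
            target_idx = _choose_targets(haps, pos, cfg, rng)
        else:
            target_idx = np.array([], dtype=np.int64)
    else:
        target_idx = np.asarray(target_idx, dtype=np.int64)
        if (target_idx >= L).any():
            raise ValueError("target index outside founder haplotype sites")
    s_vec = np.zeros(L)
    if cfg.s_array is not None:
        s_vec[target_idx] = np.asarray(cfg.s_array)[: len(target_idx)]
    else:
        s_vec[target_idx] = cfg.s

    # cumulative genetic map (Morgans) at each site
    if recomb_map is not None:
        rates = np.interp(
            pos,
            recomb_map["window_start"].to_numpy(dtype=float),
            recomb_map["rate"].to_numpy(dtype=float),
        )
    else:
        rates = np.full(L, cfg.recomb_rate_cm_mb)
    gaps = np.diff(pos, prepend=pos[0]).astype(float)
    pos_morgans = np.cumsum(gaps * rates / 1e8)

    gens = np.asarray(cfg.generations)
    T, R, N = len(gens), cfg.n_replicates, cfg.census_n
    freq = np.empty((L, R, T))
    ln_fit_per_copy = np.log1p(s_vec[target_idx])  # (1+s) per allele copy

    for rep in range(R):
        rrng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        draw = rrng.integers(0, H, size=(N, 2))
        hap_a = haps[draw[:, 0]].copy()
        hap_b = haps[draw[:, 1]].copy()
        freq[:, rep, 0] = (
            hap_a.sum(axis=0) + hap_b.sum(axis=0)
        ) / (2 * N)
        t_idx = 1
        for g in range(1, gens[-1] + 1):
            if len(target_idx):
                dosage = (
                    hap_a[:, target_idx].astype(np.int64)
                    + hap_b[:, target_idx]
                )
                w = np.exp(dosage @ ln_fit_per_copy)
                prob = w / w.sum()
            else:
                prob = np.full(N, 1.0 / N)
            p1 = rrng.choice(N, size=N, p=prob)
            p2 = rrng.choice(N, size=N, p=prob)
            new_a = _recombine(hap_a[p1], hap_b[p1], pos_morgans, rrng)
            new_b = _recombine(hap_a[p2], hap_b[p2], pos_morgans, rrng)
            hap_a, hap_b = new_a, new_b
            if t_idx < T and g == gens[t_idx]:
                freq[:, rep, t_idx] = (
                    hap_a.sum(axis=0) + hap_b.sum(axis=0)
                ) / (2 * N)
                t_idx += 1

    founder_f = haps.mean(axis=0)
    is_target = np.zeros(L, dtype=bool)
    is_target[target_idx] = True
    return TruthTable(
        chrom=np.full(L, cfg.chrom, dtype=object),
        pos=pos,
        is_target=is_target,
        s=s_vec,
        p0=founder_f,
        freq=freq,
        generations=gens,
    )


# ---------------------------------------------------------------------------
# Pool-seq sampling and synthetic block assignments


def poolseq_sample(
    truth: TruthTable,
    depth_lambda,
    seed: int,
    replicates=None,
) -> CountTensor:
    """Sample Pool-seq read counts from true allele frequencies.

    Per site x replicate x timepoint: depth ~ Poisson(lambda), rising-allele
    count ~ Binomial(depth, true frequency).  ``depth_lambda`` may be a
    scalar or an (R, T) array of per-sample means.
    """
    rng = np.random.default_rng(seed)
    L, R, T = truth.freq.shape
    lam = np.broadcast_to(np.asarray(depth_lambda, dtype=float), (R, T))
    if (lam <= 0).any():
        raise ValueError("depth_lambda must be > 0")
    depth = rng.poisson(lam[None, :, :], size=(L, R, T))
    rising = rng.binomial(depth, truth.freq)
    alleles = np.empty((L, 2), dtype=object)
    alleles[:, 0] = "A"
    alleles[:, 1] = "T"
    if replicates is None:
        replicates = np.arange(1, R + 1)
    return CountTensor(
        chrom=truth.chrom,
        pos=truth.pos,
        rising=rising,
        depth=depth,
        alleles=alleles,
        timepoints=truth.generations,
        replicates=np.asarray(replicates),
        provenance={"source": "poolseq_sample", "seed": seed},
    )


def make_blocks(
    truth: TruthTable,
    window_bp: int = 100_000,
    min_afc: float = 0.10,
    min_corr: float = 0.9,
) -> pd.DataFrame:
    """Synthetic haplotype-block assignment from simulation truth.

    Emulates blocks reconstructed by trajectory clustering: each target
    claims the sites within ``window_bp`` of it (ties to the nearer
    target) that *rise with the sweep* — replicate-mean allele-frequency
    change over the run >= ``min_afc`` — and whose per-replicate
    frequency-change profile correlates with the target's at
    >= ``min_corr`` (hitchhikers ride the sweep in the same replicates).
    Returns a TSV-ready frame with columns chrom, pos, block_id;
    non-member sites are omitted.
    """
    t_idx = np.where(truth.is_target)[0]
    if len(t_idx) == 0:
        return pd.DataFrame(columns=["chrom", "pos", "block_id"])
    t_pos = truth.pos[t_idx]
    order = np.argsort(t_pos)
    t_pos, t_idx = t_pos[order], t_idx[order]
    nearest = np.clip(
        np.searchsorted(t_pos, truth.pos), 0, len(t_pos) - 1
    )
    left = np.clip(nearest - 1, 0, len(t_pos) - 1)
    d_near = np.abs(truth.pos - t_pos[nearest])
    d_left = np.abs(truth.pos - t_pos[left])
    best = np.where(d_left < d_near, left, nearest)
    dist = np.minimum(d_left, d_near)
    mean_afc = (truth.freq[:, :, -1] - truth.freq[:, :, 0]).mean(axis=1)

    # correlation of frequency-change profiles with the assigned target
    prof = (truth.freq - truth.freq[:, :, :1]).reshape(truth.n_loci, -1)
    prof = prof - prof.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(prof, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = prof / norm[:, None]
    corr = np.einsum("ij,ij->i", unit, unit[t_idx[best]])
    corr = np.where(np.isfinite(corr), corr, 0.0)

    in_block = (dist <= window_bp) & (mean_afc >= min_afc) & (corr >= min_corr)
    in_block[t_idx] = dist[t_idx] <= window_bp  # targets always members
    return pd.DataFrame(
        {
            "chrom": truth.chrom[in_block],
            "pos": truth.pos[in_block],
            "block_id": [f"B{b:03d}" for b in best[in_block]],
        }
    )


def simulate_experiment(cfg: SimConfig, **linked_kwargs):
    """Run the configured simulation and Pool-seq sampling.

    Returns (TruthTable, CountTensor).  A convenience wrapper used by the
    pipeline and the examples.
    """
    if cfg.mode == "linked":
        truth = wf_linked(cfg, **linked_kwargs)
    else:
        truth = wf_unlinked(cfg)
    pool_seed = int(
        np.random.SeedSequence([cfg.seed, 7]).generate_state(1)[0] % 2**31
    )
    ct = poolseq_sample(truth, cfg.depth_lambda, seed=pool_seed)
    return truth, ct


def write_truth_table(truth: TruthTable, path) -> None:
    truth.to_frame().to_csv(Path(path), sep="\t", index=False)
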