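"""Wright-Fisher simulator and Pool-seq sampling checks."""

import numpy as np
import pytest

import erconcord as ec


def test_deterministic_update_is_loglinear_on_logit():
    # drift disabled: logit(p_t) - logit(p0) = t * ln(1+s) exactly
    cfg = ec.SimConfig(
        mode="unlinked", n_loci=5, n_targets=5, p0=0.1, s=0.05,
        census_n=1000, n_replicates=2, seed=1,
    )
    truth = ec.wf_unlinked(cfg, drift=False)
    logit = lambda p: np.log(p / (1 - p))
    for j, g in enumerate(truth.generations):
        np.testing.assert_allclose(
            logit(truth.freq[:, :, j]) - logit(truth.freq[:, :, 0]),
            g * np.log(1.05),
            atol=1e-10,
        )


def test_huge_population_neutral_trajectories_stay_put():
    cfg = ec.SimConfig(
        mode="neutral", n_loci=200, census_n=1_000_000, n_replicates=3,
        p0_array=np.full(200, 0.5), seed=2,
    )
    truth = ec.wf_unlinked(cfg)
    sigma = np.sqrt(0.25 * 60 / (2e6))  # ~ sqrt(t p q / 2N) upper bound
    assert np.abs(truth.freq[:, :, -1] - 0.5).max() < 3 * 6 * sigma


def test_neutral_drift_variance_matches_closed_form():
    # across-replicate variance at t=20 ~ p0 (1-p0) (1 - (1-1/2N)^t)
    N, t = 1000, 20
    cfg = ec.SimConfig(
        mode="neutral", n_loci=20_000, census_n=N, n_replicates=10, seed=3,
        generations=(0, 10, 20),
    )
    truth = ec.wf_unlinked(cfg)
    var_emp = truth.freq[:, :, 2].var(axis=1, ddof=1).mean()
    var_th = (truth.p0 * (1 - truth.p0)).mean() * (
        1 - (1 - 1 / (2 * N)) ** t
    )
    assert abs(var_emp - var_th) / var_th < 0.05


def test_neutral_martingale_mean_frequency():
    cfg = ec.SimConfig(
        mode="neutral", n_loci=20_000, census_n=500, n_replicates=10, seed=4,
    )
    truth = ec.wf_unlinked(cfg)
    drift = truth.freq[:, :, -1].mean() - truth.freq[:, :, 0].mean()
    assert abs(drift) < 0.002


class TestPoolseq:
    def test_zero_frequency_never_counted(self):
        cfg = ec.SimConfig(
            mode="neutral", n_loci=100, census_n=100, n_replicates=2,
            p0_array=np.zeros(100), seed=5,
        )
        truth = ec.wf_unlinked(cfg)
        ct = ec.poolseq_sample(truth, 50.0, seed=6)
        assert ct.rising.sum() == 0

    def test_poisson_depth_mean(self):
        cfg = ec.SimConfig(
            mode="neutral", n_loci=20_000, census_n=100, n_replicates=1,
            generations=(0, 10), seed=7,
        )
        truth = ec.wf_unlinked(cfg)
        ct = ec.poolseq_sample(truth, 80.0, seed=8)
        n = ct.depth.size
        assert abs(ct.depth.mean() - 80) < 3 * np.sqrt(80 / n)

    def test_binomial_moments_at_fixed_depth(self):
        # depth pinned at 100 (tiny-variance Poisson surrogate not used:
        # we draw the binomial directly), freq 0.3: mean 30, var 21
        rng = np.random.default_rng(9)
        counts = rng.binomial(100, 0.3, size=200_000)
        assert abs(counts.mean() - 30) < 0.1
        assert abs(counts.var() - 21) < 0.3


class TestLinked:
    @pytest.fixture(scope="class")
    def small_pool(self):
        rng = np.random.default_rng(10)
        cfg = ec.SimConfig(
            mode="linked", n_loci=400, n_targets=1, census_n=200,
            n_replicates=2, s=0.2, p0=0.1, genome_length=1_000_000, seed=10,
        )
        haps, pos = ec.simulate.founder_haplotypes(cfg, rng)
        return cfg, haps, pos

    def test_complete_linkage_hitchhiker_tracks_target(self):
        # zero recombination, hitchhiker carried by exactly the target
        # haplotypes: trajectories coincide at every generation
        H, L = 30, 5
        haps = np.zeros((H, L), dtype=np.uint8)
        haps[:6, 2] = 1  # target at freq 0.2
        haps[:6, 4] = 1  # perfect hitchhiker
        haps[10:20, 0] = 1  # unlinked-in-phase neutral site
        pos = np.array([100, 200, 300, 400, 500])
        cfg = ec.SimConfig(
            mode="linked", n_loci=L, census_n=100, n_replicates=3,
            s=0.3, recomb_rate_cm_mb=0.0, seed=11,
            generations=(0, 10, 20),
        )
        truth = ec.wf_linked(
            cfg, haplotypes=haps, positions=pos,
            target_idx=np.array([2]),
        )
        np.testing.assert_allclose(truth.freq[2], truth.freq[4])

    def test_neutral_linked_run_mean_change_near_zero(self, small_pool):
        cfg, haps, pos = small_pool
        cfg_n = ec.SimConfig(
            mode="linked", n_loci=cfg.n_loci, census_n=200, n_replicates=2,
            n_targets=0, genome_length=1_000_000, seed=12,
            generations=(0, 10, 20),
        )
        truth = ec.wf_linked(
            cfg_n, haplotypes=haps, positions=pos,
            target_idx=np.array([], dtype=int),
        )
        d = truth.freq[:, :, -1] - truth.freq[:, :, 0]
        assert abs(d.mean()) < 0.01

    def test_target_sweep_matches_deterministic_recursion(self, small_pool):
        # large census keeps drift small: the mean target trajectory
        # follows the codominant recursion within Monte-Carlo error
        cfg, haps, pos = small_pool
        cfg_big = ec.SimConfig(
            mode="linked", n_loci=cfg.n_loci, census_n=2000,
            n_replicates=3, s=0.1, p0=0.2, genome_length=1_000_000,
            seed=13, generations=(0, 10, 20),
        )
        f0 = haps.mean(axis=0)
        tgt = int(np.argmin(np.abs(f0 - 0.2)))
        truth = ec.wf_linked(
            cfg_big, haplotypes=haps, positions=pos,
            target_idx=np.array([tgt]),
        )
        p = np.full(3, f0[tgt])
        traj = [p.copy()]
        for g in range(1, 21):
            p = ec.selection_update(p, 0.1)
            if g in (10, 20):
                traj.append(p.copy())
        expected = np.stack(traj, axis=1)
        np.testing.assert_allclose(
            truth.freq[tgt].mean(axis=0), expected.mean(axis=0), atol=0.04
        )

    def test_target_site_missing_raises(self, small_pool):
        cfg, haps, pos = small_pool
        with pytest.raises(ValueError):
            ec.wf_linked(
                cfg, haplotypes=haps, positions=pos,
                target_idx=np.array([len(pos) + 5]),
            )


def test_make_blocks_assigns_nearby_rising_sites():
    L = 100
    freq = np.zeros((L, 1, 2))
    rising_sites = np.r_[18:24, 68:74]  # respond with the sweeps
    freq[rising_sites, :, 1] = 0.4
    truth = ec.TruthTable(
        chrom=np.full(L, "2", dtype=object),
        pos=np.arange(L) * 1000 + 1,
        is_target=np.isin(np.arange(L), [20, 70]),
        s=np.zeros(L),
        p0=np.full(L, 0.5),
        freq=freq,
        generations=np.array([0, 10]),
    )
    blocks = ec.make_blocks(truth, window_bp=5000, min_afc=0.10)
    assert set(blocks["block_id"]) == {"B000", "B001"}
    near = blocks[blocks["block_id"] == "B000"]["pos"]
    assert near.min() >= 20 * 1000 + 1 - 5000
    assert near.max() <= 20 * 1000 + 1 + 5000
    # every member either rises with the sweep or is the target itself
    member_idx = (blocks["pos"].to_numpy() - 1) // 1000
    ok = np.isin(member_idx, rising_sites) | np.isin(member_idx, [20, 70])
    assert ok.all()


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        ec.SimConfig(p0=1.5).validate()
    with pytest.raises(ValueError):
        ec.SimConfig(census_n=1).validate()
    with pytest.raises(ValueError):
        ec.SimConfig(depth_lambda=0).validate()
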