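"""HADR, EDHA clustering, selection-coefficient and feature tests."""

import numpy as np
import pandas as pd
import pytest

import erconcord as ec

from conftest import make_tensor


def _cand(ids, t=60):
    ids = np.asarray(ids, dtype=object)
    return ec.CandidateSet(
        timepoint=t, snp_ids=ids, pvalues=np.full(len(ids), 1e-6),
        threshold=0.01, fdr=0.05,
    )


def _ct(n=20):
    depth = np.full((n, 3, 7), 50)
    rising = np.full((n, 3, 7), 25)
    return make_tensor(rising, depth)


class TestFilterAndHadr:
    def test_full_recovery_kept_partial_dropped(self):
        ct = _ct(20)
        ids = ct.snp_ids()
        members = {"A": np.arange(10), "B": np.arange(10, 20)}
        # A fully candidate; B at 8/10 = 0.8 < 0.9 recovery
        cs = _cand(np.concatenate([ids[:10], ids[10:18]]))
        kept = ec.filter_blocks(members, ct, cs, min_recovery=0.9)
        assert set(kept) == {"A"}

    def test_recovery_just_below_threshold_dropped(self):
        ct = _ct(100)
        ids = ct.snp_ids()
        members = {"A": np.arange(100)}
        cs = _cand(ids[:89])  # 0.89 < 0.90, strict
        assert ec.filter_blocks(members, ct, cs, 0.9) == {}
        cs2 = _cand(ids[:90])
        assert set(ec.filter_blocks(members, ct, cs2, 0.9)) == {"A"}

    def test_hadr_fraction(self):
        ct = _ct(10)
        ids = ct.snp_ids()
        assert ec.hadr(np.arange(10), ct, _cand(ids[:4])) == pytest.approx(0.4)
        assert ec.hadr(np.arange(10), ct, _cand([])) == 0.0

    def test_hadr_matrix_shape_and_floor(self):
        ct = _ct(10)
        ids = ct.snp_ids()
        members = {"A": np.arange(5), "B": np.arange(5, 10)}
        cands = {20: _cand(ids[:5], 20), 60: _cand(ids, 60)}
        hm = ec.hadr_matrix(members, ct, cands)
        assert hm.shape == (2, 2)
        assert hm.loc["A", 20] == 1.0 and hm.loc["B", 20] == 0.0
        assert (hm[60] >= 0.9).all()


class TestGapStatisticAndEdha:
    def _planted(self, noise=0.05, n_per=20, seed=0):
        rng = np.random.default_rng(seed)
        gens = [10, 20, 30, 40, 50, 60]
        early = np.array([0.7, 0.85, 0.9, 0.92, 0.95, 1.0])
        late = np.array([0.05, 0.1, 0.2, 0.5, 0.8, 1.0])
        rows = []
        names = []
        for i in range(n_per):
            rows.append(np.clip(early + rng.normal(0, noise, 6), 0, 1))
            names.append(f"E{i:02d}")
        for i in range(n_per):
            rows.append(np.clip(late + rng.normal(0, noise, 6), 0, 1))
            names.append(f"L{i:02d}")
        return pd.DataFrame(rows, index=names, columns=gens)

    def test_planted_two_archetypes_recovered(self):
        hm = self._planted()
        flags = ec.find_edha(hm, k=2, early_generation=20, seed=1)
        edha = set(flags.index[flags["edha"]])
        assert edha == {f"E{i:02d}" for i in range(20)}

    def test_gap_statistic_finds_two_clusters(self):
        hm = self._planted(noise=0.03)
        k, _ = ec.gap_statistic(hm.to_numpy(), k_max=6, n_ref=20, seed=2)
        assert k == 2

    def test_identical_trajectories_no_edha(self):
        hm = pd.DataFrame(
            np.tile([0.2, 0.5, 1.0], (8, 1)), columns=[20, 40, 60]
        )
        flags = ec.find_edha(hm, early_generation=20, n_ref=10, seed=3)
        assert not flags["edha"].any()

    def test_row_permutation_invariance(self):
        hm = self._planted(seed=4)
        perm = hm.sample(frac=1, random_state=9)
        f1 = ec.find_edha(hm, k=2, early_generation=20, seed=5)
        f2 = ec.find_edha(perm, k=2, early_generation=20, seed=5)
        assert set(f1.index[f1["edha"]]) == set(f2.index[f2["edha"]])


class TestEstimateS:
    @staticmethod
    def _deterministic_traj(s, p0, times, reps=3):
        p = np.full(reps, p0)
        out = [p.copy()]
        for g in range(1, max(times) + 1):
            p = ec.selection_update(p, s)
            if g in times[1:]:
                out.append(p.copy())
        return np.stack(out, axis=1)

    def test_noiseless_trajectory_recovers_s_exactly(self):
        times = [0, 10, 20, 30, 40, 50, 60]
        traj = self._deterministic_traj(0.05, 0.1, times)
        assert ec.estimate_s(traj, times) == pytest.approx(0.05, abs=1e-12)

    def test_constant_trajectory_gives_zero(self):
        times = [0, 10, 20]
        traj = np.full((2, 3), 0.4)
        # flat trajectories never pass the AFC filter; with the filter
        # disabled the slope is exactly zero
        assert np.isnan(ec.estimate_s(traj, times, afc_threshold=0.1))
        assert ec.estimate_s(traj, times, afc_threshold=-1) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_nonresponding_replicates_excluded(self):
        times = [0, 10, 20, 30, 40, 50, 60]
        rising = self._deterministic_traj(0.05, 0.1, times, reps=1)
        flat = np.full((1, 7), 0.1)
        traj = np.vstack([rising, flat])
        assert ec.estimate_s(traj, times) == pytest.approx(0.05, abs=1e-10)

    def test_recovery_from_noisy_simulation(self):
        cfg = ec.SimConfig(
            mode="unlinked", n_loci=200, n_targets=200, p0=0.1, s=0.05,
            census_n=1000, n_replicates=10, depth_lambda=80.0, seed=41,
        )
        truth, ct = ec.simulate_experiment(cfg)
        ct = ec.polarize_rising(ct)
        f = ct.frequencies()
        times = np.asarray(ct.timepoints)
        s_hat = [
            ec.estimate_s(f[i], times, afc_threshold=0.1)
            for i in range(ct.n_snps)
        ]
        med = np.nanmedian(s_hat)
        assert 0.04 <= med <= 0.06


class TestBlockFeatures:
    def test_rising_replicates_counts_and_monotonicity(self):
        times = [0, 10, 20]
        traj = np.array(
            [[0.1, 0.15, 0.35], [0.1, 0.1, 0.16], [0.1, 0.1, 0.1]]
        )
        assert ec.rising_replicates(traj, times, 20, 0.05) == 2
        assert ec.rising_replicates(traj, times, 20, 0.10) == 1
        assert ec.rising_replicates(traj, times, 20, 0.24) == 1
        assert ec.rising_replicates(traj, times, 20, 0.26) == 0

    def test_mean_recomb_rate_overlap_weighted(self):
        recmap = pd.DataFrame(
            {
                "chrom": ["2", "2", "2"],
                "window_start": [0, 100, 200],
                "window_end": [100, 200, 300],
                "rate": [1.0, 3.0, 5.0],
            }
        )
        # span 50..250: overlaps 50, 100, 50 -> (1*50+3*100+5*50)/200 = 3.0
        from erconcord.blocks import mean_recomb_rate

        assert mean_recomb_rate("2", 50, 250, recmap) == pytest.approx(3.0)


class TestCompareFeatures:
    def _table(self, shift_rs=0.0, seed=0, n=93, n_edha=10):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "length_bp": rng.integers(10_000, 500_000, n),
                "median_start_af": rng.uniform(0.02, 0.3, n),
                "recomb_rate": rng.uniform(0.5, 4, n),
                "s20": rng.normal(0.06, 0.01, n),
                "s60": rng.normal(0.05, 0.01, n),
                "rising20": rng.integers(2, 10, n),
                "rising60": rng.integers(5, 11, n),
            }
        )
        df["r_s"] = df["s20"] / df["s60"]
        df["edha"] = np.arange(n) < n_edha
        df.loc[df["edha"], "r_s"] += shift_rs
        return df

    def test_identical_groups_nonsignificant(self):
        df = self._table()
        res = ec.compare_features(df)
        assert not res["significant"].any()

    def test_planted_rs_shift_detected_specifically(self):
        df = self._table(shift_rs=1.5, seed=1)
        res = ec.compare_features(df).set_index("feature")
        assert res.loc["r_s", "significant"]
        others = res.drop(index="r_s")
        assert others["significant"].sum() == 0

    def test_label_swap_leaves_p_unchanged(self):
        df = self._table(shift_rs=1.0, seed=2)
        res1 = ec.compare_features(df).set_index("feature")["p_raw"]
        df2 = df.copy()
        df2["edha"] = ~df2["edha"]
        res2 = ec.compare_features(df2).set_index("feature")["p_raw"]
        pd.testing.assert_series_equal(res1, res2)
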