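"""CMH / Fisher tests, neutral null and empirical FDR thresholding."""

import itertools

import numpy as np
import pytest
from scipy import stats

import erconcord as ec


class TestCMH:
    def test_balanced_table_gives_null(self):
        stat, p = ec.cmh_test(np.array([[10, 10], [10, 10]]))
        assert stat == 0 and p == 1

    def test_matches_direct_stratified_formula(self):
        # independent oracle: sum over strata of hypergeometric moments
        tables = np.array([[[12, 5], [4, 13]], [[8, 2], [3, 9]]], dtype=float)
        num = 0.0
        den = 0.0
        for t in tables:
            n = t.sum()
            e = t[0].sum() * t[:, 0].sum() / n
            v = (
                t[0].sum() * t[1].sum() * t[:, 0].sum() * t[:, 1].sum()
                / (n**2 * (n - 1))
            )
            num += t[0, 0] - e
            den += v
        expect = num**2 / den
        stat, p = ec.cmh_test(tables)
        assert stat == pytest.approx(expect, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(expect, 1), abs=1e-15)

    def test_matches_statsmodels_cmh(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        rng = np.random.default_rng(5)
        tables = rng.integers(1, 40, size=(4, 2, 2)).astype(float)
        stat, _ = ec.cmh_test(tables)
        st = sm.StratifiedTable(tables.transpose(1, 2, 0))
        ref = st.test_null_odds(correction=False).statistic
        assert stat == pytest.approx(float(ref), abs=1e-10)

    def test_duplicating_strata_doubles_statistic(self):
        t = np.array([[[12, 5], [4, 13]]], dtype=float)
        s1, _ = ec.cmh_test(t)
        s2, _ = ec.cmh_test(np.concatenate([t, t]))
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_degenerate_strata_skipped(self):
        tables = np.array([[[0, 0], [5, 7]], [[12, 5], [4, 13]]], float)
        s_mixed, _ = ec.cmh_test(tables)
        s_only, _ = ec.cmh_test(tables[1])
        assert s_mixed == pytest.approx(s_only)
        assert ec.cmh_test(np.zeros((3, 2, 2))) == (0.0, 1.0)

    def test_vectorized_agrees_with_scalar(self):
        rng = np.random.default_rng(6)
        S, K = 50, 5
        d0 = rng.integers(10, 120, size=(S, K))
        dt = rng.integers(10, 120, size=(S, K))
        a0 = rng.binomial(d0, 0.35)
        at = rng.binomial(dt, 0.5)
        vec = ec.cmh_test_counts(a0, d0, at, dt)
        for i in range(S):
            tables = np.stack(
                [
                    np.array(
                        [
                            [a0[i, k], at[i, k]],
                            [d0[i, k] - a0[i, k], dt[i, k] - at[i, k]],
                        ]
                    )
                    for k in range(K)
                ]
            )
            _, p = ec.cmh_test(tables)
            assert vec[i] == pytest.approx(p, abs=1e-10)


class TestFisher:
    def test_exact_value_by_complete_enumeration(self):
        # margins fixed at (5,5)x(5,5): enumerate all tables
        n, r1, c1 = 10, 5, 5
        pmf = {
            a: (
                stats.hypergeom.pmf(a, n, r1, c1)
            )
            for a in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
        }
        p_obs = pmf[5]
        expect = sum(v for v in pmf.values() if v <= p_obs + 1e-12)
        assert ec.fisher_test([[5, 0], [0, 5]]) == pytest.approx(
            expect, rel=1e-10
        )
        assert expect == pytest.approx(2 / 252, rel=1e-10)

    def test_uniform_table_is_null(self):
        assert ec.fisher_test([[1, 1], [1, 1]]) == 1.0

    def test_row_swap_symmetry(self):
        assert ec.fisher_test([[9, 2], [3, 8]]) == pytest.approx(
            ec.fisher_test([[3, 8], [9, 2]]), rel=1e-12
        )

    def test_vectorized_matches_scipy(self):
        rng = np.random.default_rng(7)
        d0 = rng.integers(5, 60, size=40)
        dt = rng.integers(5, 60, size=40)
        a0 = rng.binomial(d0, 0.4)
        at = rng.binomial(dt, 0.6)
        vec = ec.fisher_test_counts(a0, d0, at, dt)
        for i in range(40):
            table = [[a0[i], at[i]], [d0[i] - a0[i], dt[i] - at[i]]]
            assert vec[i] == pytest.approx(
                ec.fisher_test(table), abs=1e-10
            )

    def test_cmh_approaches_fisher_for_large_single_stratum(self):
        # K = 1: the chi-square converges to the exact test as counts
        # grow; the relative gap shrinks monotonically and is < 10% once
        # cells reach ~10^3 (the conditional exact test is conservative
        # at smaller counts)
        gaps = []
        for scale in (1, 10, 100):
            table = scale * np.array([[110, 99], [99, 110]], dtype=float)
            _, p_cmh = ec.cmh_test(table)
            p_f = ec.fisher_test(table.astype(int))
            gaps.append(abs(p_cmh - p_f) / p_f)
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.10


class TestNeutralNull:
    def test_null_pvalues_roughly_uniform(self):
        S, K = 20_000, 10
        f0 = np.full(S, 0.5)
        d = np.full((S, K), 200)
        p = ec.simulate_null_pvalues(f0, d, d, ne=10_000, t=10, seed=1)
        # discrete tests break exact uniformity; check coarse quantiles
        assert np.quantile(p, 0.01) == pytest.approx(0.01, abs=0.005)
        assert np.quantile(p, 0.5) == pytest.approx(0.5, abs=0.03)

    def test_no_drift_no_depth_variation_no_signal(self):
        S = 2000
        f0 = np.full(S, 0.5)
        d = np.full((S, 2), 5000)
        p = ec.simulate_null_pvalues(f0, d, d, ne=10**7, t=5, seed=2)
        # with Ne -> infinity the only variation is read sampling: the
        # p-value distribution must not be enriched near zero
        assert (p < 0.01).mean() < 0.02


class TestFdrThreshold:
    def test_observed_equals_null_calls_nothing(self):
        rng = np.random.default_rng(3)
        obs = rng.uniform(size=5000)
        nul = rng.uniform(size=5000)
        thr, mask, _ = ec.fdr_threshold(obs, nul, q=0.05)
        assert mask.mean() < 0.005

    def test_strong_signal_calls_everything(self):
        obs = np.full(100, 1e-12)
        nul = np.random.default_rng(4).uniform(0.1, 1, size=100)
        thr, mask, fdr = ec.fdr_threshold(obs, nul, q=0.05)
        assert mask.all()
        assert fdr == 0

    def test_mixed_ensemble_controls_fdr(self):
        rng = np.random.default_rng(5)
        signal = rng.beta(0.05, 1, size=100)
        null_obs = rng.uniform(size=900)
        obs = np.concatenate([signal, null_obs])
        labels = np.r_[np.ones(100, bool), np.zeros(900, bool)]
        nul = rng.uniform(size=9000)
        _, mask, _ = ec.fdr_threshold(obs, nul, q=0.05)
        assert mask.sum() > 20
        fdp = (~labels & mask).sum() / mask.sum()
        # binomial MC slack on top of the 5% target
        assert fdp <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / mask.sum())

    def test_candidate_sets_monotone_in_q(self):
        rng = np.random.default_rng(6)
        obs = np.concatenate(
            [rng.beta(0.1, 1, size=200), rng.uniform(size=800)]
        )
        nul = rng.uniform(size=1000)
        _, m1, _ = ec.fdr_threshold(obs, nul, q=0.01)
        _, m5, _ = ec.fdr_threshold(obs, nul, q=0.05)
        assert (m5 | ~m1).all()  # q=0.01 set subset of q=0.05 set


def test_scan_timepoint_excludes_fixed_snps(selected_experiment):
    _, truth, ct = selected_experiment
    cs = ec.scan_timepoint(ct, t=20, ne=1000.0, q=0.05, seed=8)
    tp = list(ct.timepoints)
    f = ct.frequencies()
    fixed_everywhere = (
        (f[:, :, tp.index(20)] == 1) | (f[:, :, tp.index(20)] == 0)
    ).all(axis=1)
    tested = set(cs.all_snp_ids.tolist())
    for sid in ct.snp_ids()[fixed_everywhere]:
        assert sid not in tested
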