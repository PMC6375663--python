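"""CMH / Fisher tests, filters and empirical q-values against oracles."""

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as st_h

from erpoly import detect

from conftest import make_tensor


class TestFilters:
    def test_absolute_bounds_on_total_coverage(self):
        totals = np.array([10, 50, 60, 70, 500])
        cov = np.repeat(totals[:, None, None], 2, axis=2) // 2
        rising = cov // 2
        tensor = make_tensor(rising, cov, generations=(0, 60))
        filtered, report = detect.filter_snps(
            tensor, absolute_bounds=(30, 400), min_minor_reads=0)
        assert filtered.n_snps == 3
        assert report.n_removed_low_coverage == 1
        assert report.n_removed_high_coverage == 1

    def test_minor_allele_support_rule(self):
        cov = np.full((2, 1, 2), 100)
        rising = np.array([[[9, 50]], [[10, 50]]])
        tensor = make_tensor(rising, cov, generations=(0, 60))
        filtered, report = detect.filter_snps(tensor,
                                              absolute_bounds=(0, 10_000),
                                              min_minor_reads=10)
        assert filtered.n_snps == 1
        assert report.n_removed_minor_count == 1

    def test_idempotent_with_fixed_bounds(self):
        rng = np.random.default_rng(0)
        cov = rng.integers(20, 300, size=(50, 3, 2))
        rising = rng.binomial(cov, 0.4)
        tensor = make_tensor(rising, cov, generations=(0, 60))
        once, _ = detect.filter_snps(tensor, absolute_bounds=(100, 1200))
        twice, rep2 = detect.filter_snps(once, absolute_bounds=(100, 1200))
        assert twice.n_snps == once.n_snps
        assert rep2.n_retained == rep2.n_input

    def test_empty_result_warns(self):
        cov = np.full((3, 1, 2), 10)
        tensor = make_tensor(cov // 2, cov, generations=(0, 60))
        with pytest.warns(UserWarning, match="all SNPs removed"):
            filtered, _ = detect.filter_snps(tensor,
                                             absolute_bounds=(1000, 2000))
        assert filtered.n_snps == 0


class TestCMH:
    def test_equal_proportions_give_null(self):
        anc = np.array([[10, 10]] * 3)
        evo = np.array([[10, 10]] * 3)
        chi2, p = detect.cmh_test(anc, evo)
        assert chi2 == 0.0 and p == 1.0

    def test_two_strata_hand_value(self):
        # strata (a,b,c,d) = (12,8,6,14) and (15,5,8,12): Mantel-Haenszel
        # sums evaluated by hand give chi2 = 8.3748, p = 0.0038
        anc = np.array([[12, 8], [15, 5]])
        evo = np.array([[6, 14], [8, 12]])
        chi2, p = detect.cmh_test(anc, evo)
        assert chi2 == pytest.approx(8.3748, abs=2e-4)
        assert p == pytest.approx(0.0038, abs=2e-4)

    def test_matches_statsmodels_stratified_table(self):
        from statsmodels.stats.contingency_tables import StratifiedTable
        rng = np.random.default_rng(4)
        for _ in range(10):
            anc = rng.integers(1, 30, size=(4, 2))
            evo = rng.integers(1, 30, size=(4, 2))
            tables = [np.array([[anc[i, 0], evo[i, 0]],
                                [anc[i, 1], evo[i, 1]]]) for i in range(4)]
            ref = StratifiedTable(tables).test_null_odds(correction=False)
            chi2, p = detect.cmh_test(anc, evo)
            assert chi2 == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_single_stratum_is_scaled_pearson_chi2(self):
        # with one stratum the MH statistic equals the classical 2x2
        # chi-square (no continuity correction) times (n-1)/n — the
        # hypergeometric-variance convention
        a, b, c, d = 12, 8, 6, 14
        n = a + b + c + d
        chi2, _ = detect.cmh_test(np.array([[a, b]]), np.array([[c, d]]))
        pearson = st.chi2_contingency([[a, b], [c, d]],
                                      correction=False).statistic
        assert chi2 == pytest.approx(pearson * (n - 1) / n, rel=1e-12)

    def test_all_degenerate_flagged(self):
        chi2, p = detect.cmh_test(np.array([[0, 0]]), np.array([[0, 0]]))
        assert (chi2, p) == (0.0, 1.0)
        _, _, flag = detect.cmh_many([0], [0], [0], [0])
        assert flag


class TestFisher:
    def test_balanced_table(self):
        assert detect.fisher_exact(5, 5, 5, 5) == 1.0

    def test_extreme_table_enumeration(self):
        # only the two extreme tables attain the minimal probability:
        # p = 2 / C(20, 10)
        from math import comb
        assert detect.fisher_exact(10, 0, 0, 10) == pytest.approx(
            2 / comb(20, 10), rel=1e-12)

    def test_degenerate_margin(self):
        assert detect.fisher_exact(0, 0, 5, 5) == 1.0

    @given(st_h.integers(0, 15), st_h.integers(0, 15),
           st_h.integers(0, 15), st_h.integers(0, 15))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_hypergeometric_enumeration(self, a, b, c, d):
        """Brute-force oracle: sum hypergeometric pmf over every table with
        probability <= the observed (margins <= 30)."""
        mine = detect.fisher_exact(a, b, c, d)
        M, n1, K = a + b + c + d, a + b, a + c
        if n1 == 0 or n1 == M or K == 0 or K == M:
            assert mine == 1.0
            return
        xs = np.arange(max(0, K - (M - n1)), min(n1, K) + 1)
        pmf = st.hypergeom.pmf(xs, M, K, n1)
        p_obs = st.hypergeom.pmf(a, M, K, n1)
        ref = pmf[pmf <= p_obs * (1 + 1e-7)].sum()
        assert mine == pytest.approx(min(ref, 1.0), rel=1e-9)
        assert mine == pytest.approx(
            st.fisher_exact([[a, b], [c, d]])[1], rel=1e-7)


class TestEmpiricalFDR:
    def test_observed_below_all_null_gives_zero(self):
        q = detect.empirical_fdr(np.array([1e-6]),
                                 np.array([0.5, 0.6, 0.7]), iterations=1)
        assert q[0] == 0.0

    def test_uniform_null_expectation(self):
        # observed: 10 p-values at 0.01 and 90 at 0.5; null: 100 uniforms
        # per iteration -> q(0.01) ~ (100 * 0.01) / 10 = 0.1
        rng = np.random.default_rng(9)
        iters = 400
        null = rng.random(iters * 100)
        obs = np.array([0.01] * 10 + [0.5] * 90)
        q = detect.empirical_fdr(obs, null, iterations=iters)
        assert q[0] == pytest.approx(0.1, abs=0.03)

    def test_identical_observed_get_identical_q(self):
        obs = np.full(20, 0.2)
        q = detect.empirical_fdr(obs, np.linspace(0, 1, 100), iterations=1)
        assert np.unique(q).size == 1

    def test_monotone_in_p(self):
        rng = np.random.default_rng(3)
        obs = rng.random(200)
        q = detect.empirical_fdr(obs, rng.random(1000), iterations=5)
        order = np.argsort(obs)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestNeutralNull:
    def make_tensor(self, seed=0, S=50, R=3):
        rng = np.random.default_rng(seed)
        cov = rng.integers(50, 150, size=(S, R, 2))
        p = rng.uniform(0.1, 0.9, size=S)
        rising = rng.binomial(cov, p[:, None, None])
        return make_tensor(rising, cov, generations=(0, 60))

    def test_deterministic_for_fixed_seed(self):
        t = self.make_tensor()
        a = detect.neutral_null(t, ne=300, iterations=2, seed=5)
        b = detect.neutral_null(t, ne=300, iterations=2, seed=5)
        np.testing.assert_array_equal(a["cmh"], b["cmh"])
        np.testing.assert_array_equal(a["fisher"], b["fisher"])

    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError, match="iterations"):
            detect.neutral_null(self.make_tensor(), ne=300, iterations=0)

    def test_nonpositive_ne_rejected(self):
        with pytest.raises(ValueError, match="Ne"):
            detect.neutral_null(self.make_tensor(), ne=0, iterations=1)

    def test_null_p_uniform_when_drift_negligible(self):
        # huge Ne and deep coverage: the CMH null p is approximately uniform
        rng = np.random.default_rng(11)
        S, R = 4000, 5
        cov = np.full((S, R, 2), 1000)
        p = rng.uniform(0.2, 0.8, size=S)
        rising = rng.binomial(cov, p[:, None, None])
        t = make_tensor(rising, cov, generations=(0, 60))
        null = detect.neutral_null(t, ne=2e5, iterations=1, seed=12,
                                   fisher=False)
        frac = (null["cmh"][0] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / S)
        assert abs(frac - 0.05) < 3 * se
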