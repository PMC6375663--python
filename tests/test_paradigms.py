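"""Paradigm simulators: WF engine, jackknife, QT and linked scenarios."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from erpoly import paradigms as par
from erpoly import simulate
from erpoly.paradigms import GaussianFitness, ScenarioConfig


class TestGaussianFitness:
    def test_peak_and_floor(self):
        w = GaussianFitness(0.6, 0.3, 0.5, 4.5)
        assert w(0.6) == 4.5
        assert w(0.6 + 10 * 0.3) == pytest.approx(0.5, abs=1e-6)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            GaussianFitness(0.0, 0.3, w_min=2.0, w_max=1.0)


class TestWFEngine:
    def test_absorbing_boundaries(self):
        traj = par.wf_simulate([0.0, 1.0], 0.5, n_diploid=50,
                               n_generations=20, seed=1)
        np.testing.assert_allclose(traj[0, 0], 0.0)
        np.testing.assert_allclose(traj[0, 1], 1.0)

    def test_neutral_mean_preserved(self):
        final = par.wf_simulate(0.5, 0.0, n_diploid=100, n_generations=30,
                                n_iterations=5000, seed=2, record="final")
        se = final.std() / np.sqrt(final.size)
        assert abs(final.mean() - 0.5) < 3 * se

    def test_deterministic_given_seed(self):
        a = par.wf_simulate(0.2, 0.05, n_generations=10, n_iterations=4,
                            seed=3)
        b = par.wf_simulate(0.2, 0.05, n_generations=10, n_iterations=4,
                            seed=3)
        np.testing.assert_array_equal(a, b)

    def test_invalid_population_rejected(self):
        with pytest.raises(ValueError):
            par.wf_simulate(0.5, 0.0, n_diploid=0, n_generations=5)


class TestRedundancyJackknife:
    def test_saturated_draws(self):
        res = par.redundancy_jackknife([99] * 10, 99, iterations=5, seed=1)
        np.testing.assert_allclose(res.jaccard, 1.0)
        assert (res.rfs[:, -1] == 99).all()
        assert (res.rfs[:, :-1] == 0).all()

    def test_hypergeometric_intersection_expectation(self):
        # two replicates of 53 from 99: E[intersection] = 53*53/99 = 28.37,
        # implying Jaccard about 28.4 / 77.6 = 0.366
        res = par.redundancy_jackknife([53, 53], 99, iterations=3000, seed=2)
        jac = res.jaccard.ravel()
        expect_j = (53 * 53 / 99) / (106 - 53 * 53 / 99)
        assert jac.mean() == pytest.approx(expect_j, abs=0.005)

    def test_count_exceeding_pool_rejected(self):
        with pytest.raises(ValueError):
            par.redundancy_jackknife([100], 99, iterations=1)


class TestSweepScenario:
    def test_deterministic_sweep_saturates_top_class(self):
        cfg = ScenarioConfig("sweep", p0=np.full(20, 0.3),
                             s=np.full(20, 5.0), n_iterations=10,
                             n_diploid=10_000, seed=3)
        res = par.sweep_rfs(cfg)
        assert (res.rfs[:, -1] == 20).all()

    def test_null_sweep_leaves_spectrum_empty(self):
        # s = 0 with a large population: drift cannot reach the 0.1 cutoff
        cfg = ScenarioConfig("sweep", p0=np.full(20, 0.3),
                             s=np.zeros(20), n_iterations=10,
                             n_diploid=100_000, seed=4)
        res = par.sweep_rfs(cfg)
        assert res.rfs.sum() == 0

    def test_observed_like_parameters_fill_upper_third(self):
        # p0 mostly < 0.2 and s in 0.02-0.14 at Ne ~ 290: the modal RFS
        # class falls in the upper third (most alleles rise in 7-9 reps)
        rng = np.random.default_rng(5)
        hits = 0
        for seed in range(10):
            p0 = np.clip(rng.beta(1.2, 6, 99), 0.02, 0.75)
            s = rng.uniform(0.02, 0.14, 99)
            cfg = ScenarioConfig("sweep", p0=p0, s=s, n_iterations=50,
                                 n_diploid=290, seed=seed)
            modal = np.argmax(par.sweep_rfs(cfg).rfs_mean()) + 1
            hits += modal >= 7
        assert hits >= 9

    def test_x_linked_alleles_use_their_own_ne(self):
        cfg = ScenarioConfig("sweep", p0=np.array([0.3, 0.3]),
                             s=np.zeros(2), n_iterations=50,
                             n_diploid=10_000, n_diploid_x=20,
                             x_linked=np.array([False, True]), seed=6)
        res = par.sweep_rfs(cfg)
        # only the X allele (tiny Ne -> strong drift) can cross the cutoff
        assert res.rfs.sum() > 0


class TestQTScenario:
    FIT = GaussianFitness(0.6, 0.3, 0.5, 4.5)

    def test_flat_fitness_reduces_to_drift(self):
        flat = GaussianFitness(0.5, 1e6, 0.5, 4.5)
        final = par.qt_simulate(np.full(30, 0.3), flat, n_diploid=300,
                                n_generations=20, n_populations=40, seed=7)
        se = final.std() / np.sqrt(final.size)
        assert abs(final.mean() - 0.3) < 4 * se

    def test_population_below_optimum_responds_upward(self):
        # mean initial phenotype ~0.18 < optimum 0.6: rising alleles gain
        rng = np.random.default_rng(8)
        p0 = np.clip(rng.beta(1.2, 6, 99), 0.02, 0.75)
        traj = par.qt_simulate(p0, self.FIT, n_diploid=300,
                               n_generations=10, n_populations=20, seed=9,
                               record="trajectory")
        gains = (traj[:, :, -1] - traj[:, :, 0]).mean(axis=1)
        assert (gains > 0).sum() >= 19

    def test_selection_fades_at_optimum(self):
        # population fixed at the optimum phenotype: all fitnesses equal
        p0 = np.full(10, 0.6)  # mean dosage 0.6 = z_opt
        traj = par.qt_simulate(p0, self.FIT, n_diploid=500,
                               n_generations=10, n_populations=30, seed=10,
                               record="trajectory")
        drift = (traj[:, :, -1] - traj[:, :, 0]).mean()
        assert abs(drift) < 0.01


class TestIndividualEngine:
    def make_panel(self, rate=2.0, n_snps=40, p0=0.2):
        panel = simulate.generate_founder_panel(
            n_haplotypes=100, n_snps=n_snps,
            chrom_lengths={"2L": 1_000_000}, recombination_rate=rate,
            seed=11)
        panel, ledger = simulate.plant_blocks(
            panel, n_blocks=1, markers_per_block=2, span_bp=900_000,
            target_p0s=p0, seed=12)
        return panel, ledger

    def test_zero_recombination_matches_wf_engine(self):
        panel, ledger = self.make_panel(rate=0.0)
        locus = [int(ledger.blocks[0].marker_idx[0])]
        ind = par.individual_simulate(panel, locus, s=[0.08], n_diploid=300,
                                      n_generations=60, n_replicates=400,
                                      p0=[0.2], seed=13)[:, 0, 0]
        wf = par.wf_simulate(0.2, 0.08, n_diploid=300, n_generations=60,
                             n_iterations=400, seed=14,
                             record="final").ravel()
        assert ks_2samp(ind, wf).pvalue > 0.01

    def test_hitchhiking_of_linked_neutral_locus(self):
        panel, ledger = self.make_panel(rate=0.01, n_snps=40)
        b = ledger.blocks[0]
        selected = int(b.marker_idx[0])
        neutral = int(b.marker_idx[1])  # perfectly associated at start
        out = par.individual_simulate(
            panel, [selected, neutral], s=[0.3, 0.0], n_diploid=300,
            n_generations=40, n_replicates=30,
            record_generations=[0, 40], seed=15)
        dp_neutral = np.abs(out[:, 1, 1] - out[:, 0, 1]).mean()
        null = par.wf_simulate(b.p0, 0.0, n_diploid=300, n_generations=40,
                               n_iterations=2000, seed=16, record="final")
        dp_null = np.abs(null - b.p0).mean()
        assert dp_neutral > 2 * dp_null

    def test_absent_selected_position_rejected(self):
        panel, _ = self.make_panel()
        with pytest.raises(ValueError, match="absent"):
            par.individual_simulate(panel, [10_000], s=[0.1])

    def test_qt_linked_standardized_scale_responds(self):
        panel, ledger = self.make_panel(p0=0.1)
        loci = np.arange(0, panel.n_snps, 4)
        fit = GaussianFitness(-1.3, 1.2, 0.5, 4.5)
        out = par.individual_simulate(
            panel, loci, mode="qt", fitness=fit, qt_scale="standardized",
            n_diploid=300, n_generations=20, n_replicates=5,
            record_generations=[0, 20], seed=17)
        # optimum below the gen-0 mean (in SD units): dosage must fall
        assert (out[:, 1, :].mean() - out[:, 0, :].mean()) < 0


def test_scenario_runs_reproducible():
    rng = np.random.default_rng(0)
    p0 = rng.uniform(0.05, 0.3, 30)
    s = rng.uniform(0.02, 0.14, 30)
    a = par.sweep_rfs(ScenarioConfig("sweep", p0, s, n_iterations=20,
                                     seed=21))
    b = par.sweep_rfs(ScenarioConfig("sweep", p0, s, n_iterations=20,
                                     seed=21))
    np.testing.assert_array_equal(a.rfs, b.rfs)
    np.testing.assert_array_equal(a.jaccard, b.jaccard)
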