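"""Compare sweep, redundancy and QT paradigms via the RFS.

Generates "observed" data under the quantitative-trait paradigm, simulates
all three scenarios (100 iterations each), and scores them against the
observed replicate frequency spectrum with the summed squared difference.
"""

import numpy as np

from erpoly import compare, paradigms

rng = np.random.default_rng(5)
L, R = 99, 10
p0 = np.clip(rng.beta(1.2, 6, L), 0.02, 0.75)  # mostly below 0.2
s = rng.uniform(0.02, 0.14, L)
fitness = paradigms.GaussianFitness(z_opt=0.6, sigma_w=0.3,
                                    w_min=0.5, w_max=4.5)

# observed data: one QT draw (alleles of equal effect, shifted optimum)
final = paradigms.qt_simulate(p0, fitness, n_diploid=300, n_generations=60,
                              n_populations=R, seed=6)
observed = (final.T - p0[:, None]) >= 0.1  # presence: rise of >= 0.1

scenarios = {
    "sweep": paradigms.sweep_rfs(paradigms.ScenarioConfig(
        "sweep", p0, s, n_iterations=100, n_diploid=290, seed=7)),
    "qt": paradigms.qt_rfs(paradigms.ScenarioConfig(
        "qt", p0, fitness=fitness, n_iterations=100, seed=8)),
    "redundancy": paradigms.redundancy_jackknife(
        observed.sum(axis=0).tolist(), L, iterations=100, seed=9),
}
report = compare.scenario_comparison(observed, scenarios)

print("observed RFS (alleles per replicate-count class 1..10):")
print(" ", report.observed_rfs.counts)
for name in report.ranking:
    print(f"  {name:<11} mean SSE = {report.mean_sse[name]:9.1f}   "
          f"mean Jaccard = {scenarios[name].jaccard.mean():.3f}")
print(f"best-fitting paradigm: {report.best_scenario}")
# Sweeps concentrate alleles in 7-10 replicates (high Jaccard); the QT and
# redundancy paradigms reproduce the heterogeneous spread of the observed
# data, so their SSE against the observed RFS is far smaller.
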