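"""Shared fixtures: small synthetic tensors and one planted experiment."""

import numpy as np
import pandas as pd
import pytest

from erpoly import simulate
from erpoly.io import AlleleCountTensor


def make_tensor(rising, coverage, generations=(0, 60), replicates=None,
                chrom="2L"):
    """Tensor from explicit (S, R, G) count arrays with synthetic SNP keys."""
    rising = np.asarray(rising)
    coverage = np.asarray(coverage)
    S, R, G = rising.shape
    if replicates is None:
        replicates = [f"R{i+1}" for i in range(R)]
    snps = pd.DataFrame({
        "chrom": [chrom] * S,
        "pos": np.arange(1, S + 1) * 1000,
        "ref": ["A"] * S,
        "rising": ["T"] * S,
        "other": ["A"] * S,
    })
    return AlleleCountTensor(snps=snps, replicates=list(replicates),
                             generations=np.asarray(generations),
                             rising_count=rising, coverage=coverage)


def tensor_from_freq(freq, depth=100, generations=None, seed=0):
    """Tensor whose counts realize the given frequencies at fixed depth."""
    freq = np.asarray(freq, dtype=float)
    S, R, G = freq.shape
    if generations is None:
        generations = np.arange(G) * 10
    cov = np.full(freq.shape, depth, dtype=np.int64)
    rising = np.round(freq * depth).astype(np.int64)
    return make_tensor(rising, cov, generations=generations)


@pytest.fixture(scope="session")
def planted_experiment():
    """A small linked E&R experiment with 5 planted selected blocks."""
    chroms = {"2L": 3_500_000, "3L": 3_500_000}
    panel = simulate.generate_founder_panel(
        n_haplotypes=200, n_snps=3600, chrom_lengths=chroms, seed=11)
    panel2, ledger = simulate.plant_blocks(
        panel, n_blocks=5, markers_per_block=25,
        span_bp=[100_000, 200_000, 300_000, 200_000, 400_000],
        target_p0s=[0.10, 0.15, 0.20, 0.10, 0.15],
        selection_coefficients=[0.06, 0.07, 0.08, 0.09, 0.10],
        min_gap_bp=1_200_000, seed=12)
    tensor, realized = simulate.simulate_experiment(
        panel2, ledger, n_diploid=300, n_replicates=10, seed=13)
    return {"panel": panel2, "ledger": realized, "tensor": tensor}
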