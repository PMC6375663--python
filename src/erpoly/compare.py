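"""Paradigm comparison via the replicate frequency spectrum.

The replicate frequency spectrum (RFS) counts selected alleles by the
number of replicates in which they rise; its shape separates adaptive
paradigms (sweeps concentrate mass at high replicate counts, redundancy
spreads it).  Simulated scenarios are scored against observed data with the
summed squared difference of RFS class counts, and replicate similarity is
measured with pairwise Jaccard indices of the selected-allele sets.  The
folded site-frequency-spectrum contrast tests whether selected markers
segregate at different ancestral frequencies than non-selected SNPs
(two-sided Kolmogorov-Smirnov).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, ks_2samp

from .paradigms import ParadigmResult

__all__ = [
    "RFSpectrum",
    "ComparisonReport",
    "rfs",
    "sse",
    "jaccard_matrix",
    "folded_sfs_contrast",
    "scenario_comparison",
]


@dataclass
class RFSpectrum:
    """Counts of alleles present in exactly k = 1..R replicates.

    Alleles present in zero replicates are excluded from the spectrum (the
    class-0 count is kept separately for completeness).
    """

    counts: np.ndarray
    n_alleles: int
    n_zero: int = 0
    method: int | None = None

    @property
    def n_replicates(self) -> int:
        return self.counts.size

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts,
                         index=np.arange(1, self.n_replicates + 1),
                         name="n_alleles")


def rfs(presence: np.ndarray, method: int | None = None) -> RFSpectrum:
    """Replicate frequency spectrum of a boolean presence matrix
    (alleles x replicates)."""
    presence = np.asarray(presence, dtype=bool)
    if presence.ndim != 2:
        raise ValueError("presence must be 2-D (alleles x replicates)")
    L, R = presence.shape
    k = presence.sum(axis=1)
    counts = np.array([(k == c).sum() for c in range(1, R + 1)])
    return RFSpectrum(counts=counts, n_alleles=L, n_zero=int((k == 0).sum()),
                      method=method)


def sse(observed, expected) -> float:
    """Sum over RFS classes of squared (observed - expected) count
    differences."""
    obs = observed.counts if isinstance(observed, RFSpectrum) else observed
    exp = expected.counts if isinstance(expected, RFSpectrum) else expected
    obs = np.asarray(obs, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("RFS length mismatch")
    return float(((obs - exp) ** 2).sum())


def jaccard_matrix(presence: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard similarity of the replicate selected-allele sets.

    J(i, j) = |A_i & A_j| / |A_i | A_j|; two empty sets give J = 1 (the
    degenerate case is flagged by the caller's context, not an error).
    """
    P = np.asarray(presence, dtype=float)  # (alleles, R)
    inter = P.T @ P
    sizes = P.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = inter / union
    J[union == 0] = 1.0
    return J


def pairwise_jaccard(presence: np.ndarray) -> np.ndarray:
    """Upper-triangle pairwise Jaccard values (R choose 2 vector)."""
    J = jaccard_matrix(presence)
    iu = np.triu_indices(J.shape[0], k=1)
    return J[iu]


def folded_sfs_contrast(selected_freqs, nonselected_freqs,
                        bins: int = 20):
    """Contrast the folded SFS of selected markers vs non-selected SNPs.

    Frequencies are folded to the minor allele, min(p, 1 - p); the KS
    statistic D = sup |ECDF1 - ECDF2| and its two-sided p-value are
    computed on the unbinned folded values; binned spectra (density) are
    returned for plotting.
    """
    sel = np.asarray(selected_freqs, dtype=float)
    non = np.asarray(nonselected_freqs, dtype=float)
    sel = sel[np.isfinite(sel)]
    non = non[np.isfinite(non)]
    if sel.size == 0 or non.size == 0:
        raise ValueError("both SNP classes must be non-empty")
    fold_sel = np.minimum(sel, 1.0 - sel)
    fold_non = np.minimum(non, 1.0 - non)
    edges = np.linspace(0, 0.5, bins + 1)
    h_sel = np.histogram(fold_sel, bins=edges, density=True)[0]
    h_non = np.histogram(fold_non, bins=edges, density=True)[0]
    res = ks_2samp(fold_sel, fold_non, method="asymp")
    return h_sel, h_non, float(res.statistic), float(res.pvalue)


@dataclass
class ComparisonReport:
    """Observed-vs-scenarios comparison assembled by
    :func:`scenario_comparison`."""

    observed_rfs: RFSpectrum
    observed_jaccard: np.ndarray  # R x R matrix
    sse_distributions: dict[str, np.ndarray]
    jaccard_distributions: dict[str, np.ndarray]
    mean_sse: dict[str, float]
    ranking: list[str]
    anova: dict = field(default_factory=dict)

    @property
    def best_scenario(self) -> str:
        return self.ranking[0]


def scenario_comparison(observed_presence: np.ndarray,
                        scenario_results: dict[str, ParadigmResult],
                        tukey: bool = False) -> ComparisonReport:
    """Score each simulated scenario against the observed presence matrix.

    Per scenario, the per-iteration SSE against the observed RFS and the
    per-iteration pairwise Jaccard values are collected; scenarios are
    ranked by mean SSE (smaller = better fit).  A one-way ANOVA across the
    scenario SSE distributions (and optionally Tukey's HSD, delegated to
    statsmodels) is attached.
    """
    observed = rfs(observed_presence)
    R = observed.n_replicates
    for name, res in scenario_results.items():
        if res.n_replicates != R:
            raise ValueError(f"scenario {name!r} has {res.n_replicates} "
                             f"replicates, observed has {R}")
    sse_d = {name: res.sse_distribution(observed.counts)
             for name, res in scenario_results.items()}
    jac_d = {name: res.jaccard.ravel()
             for name, res in scenario_results.items()}
    mean_sse = {name: float(v.mean()) for name, v in sse_d.items()}
    ranking = sorted(mean_sse, key=mean_sse.get)
    anova: dict = {}
    if len(sse_d) >= 2:
        stat, p = f_oneway(*sse_d.values())
        anova = {"F": float(stat), "p": float(p)}
        if tukey:
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            values = np.concatenate(list(sse_d.values()))
            labels = np.concatenate(
                [[name] * v.size for name, v in sse_d.items()])
            anova["tukey"] = pairwise_tukeyhsd(values, labels)
    return ComparisonReport(
        observed_rfs=observed,
        observed_jaccard=jaccard_matrix(observed_presence),
        sse_distributions=sse_d,
        jaccard_distributions=jac_d,
        mean_sse=mean_sse,
        ranking=ranking,
        anova=anova,
    )
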