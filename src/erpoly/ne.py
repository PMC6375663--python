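"""Temporal effective-population-size estimation from Pool-Seq data.

Drift shifts allele frequencies between two time points by an amount
governed by the effective size Ne.  The standardized frequency change

    Fc = (x - y)^2 / ((x + y)/2 - x*y)

(the Jorde-Ryman-style kernel, robust at intermediate frequencies) is
averaged over windows of SNPs, corrected for the sampling noise added by
pooling individuals and by finite read depth, and inverted to
``Ne = t / (2 F')``.  Windowed estimates are summarized as the per-replicate
median and the across-replicate mean of medians.  X-chromosome data should
be passed separately (no ploidy rescaling happens inside the estimator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AlleleCountTensor

__all__ = ["NeEstimate", "temporal_f", "estimate_ne", "estimate_ne_summary"]


def temporal_f(x, y):
    """Standardized squared frequency change between two time points.

    ``Fc = (x - y)^2 / ((x + y)/2 - x y)``; NaN where the denominator is 0
    (the SNP is skipped and counted by the caller).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any((x < 0) | (x > 1) | (y < 0) | (y > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    den = (x + y) / 2.0 - x * y
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = (x - y) ** 2 / den
    return np.where(den > 0, fc, np.nan)


@dataclass
class NeEstimate:
    replicate: object
    window_ne: np.ndarray  # inf where the corrected F' was <= 0
    window_fc: np.ndarray
    t: int
    n_snps_used: int
    n_snps_skipped: int

    @property
    def median_ne(self) -> float:
        finite = self.window_ne[np.isfinite(self.window_ne)]
        if self.window_ne.size and finite.size < self.window_ne.size / 2:
            return np.inf
        return float(np.median(self.window_ne)) if self.window_ne.size \
            else np.nan


def estimate_ne(
    tensor: AlleleCountTensor,
    replicate,
    window: int = 1000,
    generations: tuple[int, int] | None = None,
    plan: str = "II",
    pool_size: int | None = None,
    census_n: int | None = None,
) -> NeEstimate:
    """Windowed temporal Ne estimate for one replicate.

    Windows of ``window`` consecutive SNPs (final window may be partial)
    contribute one estimate each: the window's pooled Fc (summed numerator
    over summed denominator, which is stable for rare alleles) is corrected
    for two-stage sampling at both time points (1/(2*pool_size) for the
    pooled individuals when applicable, plus 1/depth for read sampling,
    using the window's mean depth), and sampling plan I additionally
    subtracts 1/(2*census_n).  ``Ne = t / (2 F')``; windows with F' <= 0 are
    reported as infinite.  SNPs fixed at both time points are excluded.
    """
    if plan not in ("I", "II"):
        raise ValueError("plan must be 'I' or 'II'")
    if plan == "I" and census_n is None:
        raise ValueError("plan I requires census_n")
    if generations is None:
        generations = (int(tensor.generations[0]), int(tensor.generations[-1]))
    g0, g1 = generations
    t = g1 - g0
    if t <= 0:
        raise ValueError("elapsed generations t must be positive")
    ri = list(tensor.replicates).index(replicate)
    i0, i1 = tensor.gen_index(g0), tensor.gen_index(g1)
    freq = tensor.frequency()
    x = freq[:, ri, i0]
    y = freq[:, ri, i1]
    d0 = tensor.coverage[:, ri, i0].astype(float)
    d1 = tensor.coverage[:, ri, i1].astype(float)

    usable = np.isfinite(x) & np.isfinite(y)
    den_all = np.where(usable, (x + y) / 2.0 - x * y, np.nan)
    good = usable & (den_all > 0)  # fixed-at-both-ends SNPs excluded
    skipped = int((~good).sum())
    num = (x[good] - y[good]) ** 2
    den = den_all[good]
    d0, d1 = d0[good], d1[good]

    n_windows = max(1, int(np.ceil(num.size / window))) if num.size else 0
    window_ne = np.empty(n_windows)
    window_fc = np.empty(n_windows)
    for w in range(n_windows):
        sl = slice(w * window, (w + 1) * window)
        # pooled ratio over the window's SNPs (stable for rare alleles,
        # unlike the mean of per-SNP Fc ratios)
        fbar = float(num[sl].sum() / den[sl].sum())
        corr = 1.0 / np.mean(d0[sl]) + 1.0 / np.mean(d1[sl])
        if pool_size is not None:
            corr += 2.0 * (1.0 / (2.0 * pool_size))
        if plan == "I":
            corr += 1.0 / (2.0 * census_n)
        fprime = fbar - corr
        window_fc[w] = fbar
        window_ne[w] = t / (2.0 * fprime) if fprime > 0 else np.inf
    return NeEstimate(replicate=replicate, window_ne=window_ne,
                      window_fc=window_fc, t=t, n_snps_used=int(num.size),
                      n_snps_skipped=skipped)


def estimate_ne_summary(tensor: AlleleCountTensor, **kwargs) -> dict:
    """Per-replicate windowed estimates plus the headline value: the mean
    over replicates of the per-replicate median window Ne."""
    per_rep = {rep: estimate_ne(tensor, rep, **kwargs)
               for rep in tensor.replicates}
    medians = np.array([e.median_ne for e in per_rep.values()])
    finite = medians[np.isfinite(medians)]
    headline = float(finite.mean()) if finite.size else np.inf
    return {"per_replicate": per_rep, "medians": medians,
            "ne": headline}
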