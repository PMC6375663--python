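"""Selection-coefficient inference and presence calls for selected alleles.

A selected allele (reconstructed haplotype block) is summarized per
replicate by the median frequency trajectory of its marker SNPs.  Assuming
codominance (genotype fitnesses 1, 1 + s/2, 1 + s), the selection
coefficient is estimated from the time series by a least-squares fit of
logit(p_t) against generation — the per-generation logit increment is
ln(1 + s/2) to first order — refined by one-dimensional least squares
against the exact deterministic selection recursion.

Whether an allele is "present" (contributing to adaptation) in a replicate
is decided by one of six methods: fixed frequency-increase cutoffs of 0.1
(method 1) or 0.2 (method 2) at the final generation; allele-specific
cutoffs from the lower 5% (method 3) or 10% (method 4) tail of the
frequency-change distribution under per-allele Wright-Fisher sweep
simulations; and core-region variants of methods 1/2 (methods 5/6) that
re-estimate p0 and s on the stringently correlated sub-cluster with the
largest median s.  The median s over the present replicates is reported as
the allele's s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._rng import child_rng
from .paradigms import selection_update, wf_simulate

__all__ = [
    "SelectedAllele",
    "CoreRegion",
    "MethodResult",
    "deterministic_trajectory",
    "estimate_s",
    "presence_calls",
    "core_region",
]


# ---------------------------------------------------------------------------
# deterministic trajectory and s estimation


def deterministic_trajectory(p0: float, s: float, h: float = 0.5,
                             n_generations: int = 60) -> np.ndarray:
    """Deterministic diploid selection trajectory over generations 0..t.

    Genotype fitnesses are 1, 1+hs, 1+s; for h = 1/2 the mean fitness
    simplifies to 1 + s*p.  p0 = 0 and p0 = 1 are absorbing.
    """
    if s <= -1:
        raise ValueError("s must exceed -1")
    out = np.empty(n_generations + 1)
    out[0] = p0
    for t in range(1, n_generations + 1):
        out[t] = selection_update(out[t - 1], s, h)
    return out


def _logit(p):
    return np.log(p / (1.0 - p))


def estimate_s(freqs, generations, h: float = 0.5, coverage=None,
               refine: bool = True) -> float:
    """Estimate s from a frequency time series under codominance.

    Frequencies are clamped to [1/(2*coverage), 1 - 1/(2*coverage)] before
    the logit (Pool-Seq zeros are sampling artifacts); the closed-form logit
    slope b maps to ``s = 2 (e^b - 1)`` and initializes a bounded
    least-squares refinement against the exact selection recursion, with the
    first observed frequency as the trajectory start.  A trajectory fixed at
    0 or 1 throughout is uninformative and yields NaN; monotone decreasing
    trajectories yield s < 0.
    """
    f = np.asarray(freqs, dtype=float)
    gens = np.asarray(generations, dtype=float)
    ok = np.isfinite(f)
    f, gens = f[ok], gens[ok]
    if f.size < 2:
        return np.nan
    if np.all(f <= 0.0) or np.all(f >= 1.0):
        return np.nan
    eps = 1.0 / (2.0 * float(coverage)) if coverage else 1e-6
    fc = np.clip(f, eps, 1.0 - eps)
    if np.allclose(fc, fc[0], atol=1e-12):
        return 0.0
    b, a = np.polyfit(gens, _logit(fc), 1)
    s0 = float(np.clip(2.0 * (np.exp(b) - 1.0), -0.95, 10.0))
    if not refine:
        return s0

    t0 = gens[0]
    steps = (gens - t0).astype(int)

    def sse(theta):
        # joint (logit p0, s) fit: treating the noisy first observation as
        # the exact start would attenuate s (errors in variables)
        lp0, s = theta
        if s <= -0.95:
            return np.inf
        p = 1.0 / (1.0 + np.exp(-lp0))
        tot = 0.0
        last = 0
        for step, target in zip(steps, fc):
            for _ in range(step - last):
                p = _update_scalar(p, s, h)
            last = step
            tot += (p - target) ** 2
        return tot

    res = minimize(sse, x0=[a + b * t0, s0], method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-14})
    return float(res.x[1])


def _update_scalar(p: float, s: float, h: float) -> float:
    q = 1.0 - p
    num = p * p * (1.0 + s) + p * q * (1.0 + h * s)
    wbar = num + p * q * (1.0 + h * s) + q * q
    return num / wbar if wbar > 0 else p


# ---------------------------------------------------------------------------
# selected alleles and presence methods


@dataclass
class SelectedAllele:
    """Per-replicate trajectory summary of one reconstructed block.

    ``trajectories`` is (R, G): the median marker frequency per replicate
    and generation.  ``sub_trajectories`` optionally carries the round-1
    sub-cluster trajectories (list of (R, G) arrays with their marker
    indices) used by the core-region methods.
    """

    allele_id: int
    trajectories: np.ndarray
    generations: np.ndarray
    sub_clusters: list = field(default_factory=list)  # [(marker_idx, (R,G))]
    coverage: float | None = None

    @property
    def n_replicates(self) -> int:
        return self.trajectories.shape[0]

    @property
    def p0(self) -> float:
        """Starting frequency: across-replicate mean at the first sample."""
        return float(np.nanmean(self.trajectories[:, 0]))

    def afc(self) -> np.ndarray:
        return self.trajectories[:, -1] - self.trajectories[:, 0]


@dataclass
class CoreRegion:
    marker_idx: np.ndarray
    trajectories: np.ndarray
    p0: float
    s: float
    tie_flag: bool = False
    fallback_whole_block: bool = False


@dataclass
class MethodResult:
    method: int
    presence: np.ndarray  # (R,) bool
    s_rep: np.ndarray  # per-replicate estimates (NaN where uninformative)
    s: float  # median over present replicates, NaN if none present
    p0: float
    thresholds: np.ndarray  # per-replicate AFC threshold used

    @property
    def replicate_frequency(self) -> int:
        return int(self.presence.sum())


def _s_per_replicate(traj: np.ndarray, gens, coverage=None) -> np.ndarray:
    return np.array([estimate_s(traj[r], gens, coverage=coverage)
                     for r in range(traj.shape[0])])


def core_region(allele: SelectedAllele, rise_threshold: float = 0.1
                ) -> CoreRegion:
    """Pick the stringent sub-cluster with the largest median s.

    For each round-1 sub-cluster, the median s over replicates whose
    frequency rise meets ``rise_threshold`` is computed; the region with the
    largest median s becomes the core (ties: the larger sub-cluster, with a
    flag).  With no sub-cluster having any qualifying replicate, the whole
    block is the core, flagged.
    """
    gens = allele.generations
    best = None  # (median_s, size, idx, traj, tie)
    for marker_idx, traj in allele.sub_clusters:
        afc = traj[:, -1] - traj[:, 0]
        present = afc >= rise_threshold
        if not present.any():
            continue
        s_rep = _s_per_replicate(traj[present], gens,
                                 coverage=allele.coverage)
        med = float(np.nanmedian(s_rep))
        if np.isnan(med):
            continue
        size = len(marker_idx)
        if best is None or (med, size) > (best[0], best[1]):
            tie = best is not None and med == best[0]
            best = (med, size, marker_idx, traj, tie)
        elif med == best[0] and size == best[1]:
            best = (best[0], best[1], best[2], best[3], True)
    if best is None:
        traj = allele.trajectories
        return CoreRegion(marker_idx=np.arange(0), trajectories=traj,
                          p0=float(np.nanmean(traj[:, 0])), s=np.nan,
                          fallback_whole_block=True)
    med, _, marker_idx, traj, tie = best
    return CoreRegion(marker_idx=np.asarray(marker_idx),
                      trajectories=traj,
                      p0=float(np.nanmean(traj[:, 0])), s=med, tie_flag=tie)


_METHOD_THRESHOLD = {1: 0.1, 2: 0.2, 5: 0.1, 6: 0.2}
_METHOD_TAIL = {3: 0.05, 4: 0.10}


def presence_calls(
    allele: SelectedAllele,
    method: int,
    ne=None,
    n_sims: int = 1000,
    seed: int = 0,
) -> MethodResult:
    """Presence of a selected allele in each replicate under one method.

    Methods 1/2: frequency increase at the final generation of at least 0.1
    / 0.2 (inclusive).  Methods 3/4: the per-replicate threshold is the
    lower 5% / 10% quantile of the frequency-change distribution under
    ``n_sims`` Wright-Fisher sweep simulations at the allele's p0 with the
    highest per-replicate s and the replicate-specific Ne.  Methods 5/6:
    methods 1/2 evaluated on the core region's trajectory, p0 and s.
    """
    gens = allele.generations
    R = allele.n_replicates
    traj = allele.trajectories
    p0 = allele.p0
    if method in (5, 6):
        core = core_region(allele,
                           rise_threshold=_METHOD_THRESHOLD[method])
        traj = core.trajectories
        p0 = core.p0

    afc = traj[:, -1] - traj[:, 0]
    if method in (1, 2, 5, 6):
        thr = np.full(R, _METHOD_THRESHOLD[method])
    elif method in (3, 4):
        if ne is None:
            raise ValueError("methods 3/4 require Ne")
        if n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        s_all = _s_per_replicate(traj, gens, coverage=allele.coverage)
        s_max = np.nanmax(s_all) if np.isfinite(s_all).any() else 0.0
        ne_arr = np.broadcast_to(np.asarray(ne, dtype=float), (R,))
        rng = child_rng(seed, "presence_sims", allele.allele_id)
        t = int(gens[-1] - gens[0])
        final = wf_simulate(p0, s_max, n_diploid=ne_arr,
                            n_generations=t, n_replicates=R,
                            n_iterations=n_sims, rng=rng,
                            record="final")  # (sims, 1, R)
        sim_afc = final[:, 0, :] - p0
        thr = np.quantile(sim_afc, _METHOD_TAIL[method], axis=0)
    else:
        raise ValueError(f"unknown method {method}")

    presence = afc >= thr
    s_rep = np.full(R, np.nan)
    if presence.any():
        s_rep[presence] = _s_per_replicate(traj[presence], gens,
                                           coverage=allele.coverage)
    s_med = float(np.nanmedian(s_rep[presence])) if presence.any() else np.nan
    return MethodResult(method=method, presence=presence, s_rep=s_rep,
                        s=s_med, p0=p0, thresholds=thr)
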