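"""Forward simulation of competing adaptive paradigms.

Replicated E&R experiments can distinguish modes of polygenic adaptation by
the *replicate frequency spectrum* (RFS): the distribution of the number of
replicates in which each selected allele rises.  This module simulates the
competing generative paradigms

* ``sweep`` — every allele has a fixed selection coefficient and rises
  independently in every replicate where drift does not lose it
  (frequency-based Wright-Fisher engine, optionally with linkage through the
  individual-based engine);
* ``redundancy`` — more beneficial alleles segregate than are needed, so
  each replicate succeeds with a random subset (delete-d jackknife null);
* ``qt`` — alleles contribute equally to a quantitative trait under Gaussian
  stabilizing selection around a shifted optimum, so selection fades as the
  population mean approaches the optimum (with or without linkage).

Each scenario yields per-iteration RFS and pairwise Jaccard distributions
(:class:`ParadigmResult`) that downstream code contrasts with observed data
via the summed squared RFS difference.

Genotype fitnesses are parameterized 1, 1+hs, 1+s with codominance h = 1/2
unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import HaplotypePanel

__all__ = [
    "GaussianFitness",
    "ScenarioConfig",
    "ParadigmResult",
    "selection_update",
    "wf_simulate",
    "sweep_rfs",
    "redundancy_jackknife",
    "qt_simulate",
    "qt_rfs",
    "individual_simulate",
    "presence_to_result",
]


# ---------------------------------------------------------------------------
# fitness and configuration containers


@dataclass(frozen=True)
class GaussianFitness:
    """Gaussian stabilizing-selection fitness of a phenotype z.

    ``w(z) = w_min + (w_max - w_min) * exp(-(z - z_opt)^2 / (2 sigma_w^2))``

    so fitness peaks at ``w_max`` on the optimum and decays to the floor
    ``w_min`` far from it.
    """

    z_opt: float
    sigma_w: float
    w_min: float = 0.5
    w_max: float = 4.5

    def __post_init__(self) -> None:
        if not (self.w_max > self.w_min > 0):
            raise ValueError("require w_max > w_min > 0")
        if self.sigma_w <= 0:
            raise ValueError("sigma_w must be positive")

    def __call__(self, z: np.ndarray | float) -> np.ndarray | float:
        z = np.asarray(z, dtype=float)
        return self.w_min + (self.w_max - self.w_min) * np.exp(
            -((z - self.z_opt) ** 2) / (2.0 * self.sigma_w**2))


@dataclass
class ScenarioConfig:
    """Parameters of one paradigm-simulation scenario.

    ``n_diploid`` may be a scalar or a per-replicate vector of effective
    sizes; ``x_linked`` optionally marks alleles simulated with the
    X-specific size ``n_diploid_x``.  ``presence_threshold`` is the allele
    frequency change at the final generation that counts an allele as
    present in a replicate (inclusive).
    """

    scenario: str
    p0: np.ndarray
    s: np.ndarray | None = None
    n_replicates: int = 10
    n_generations: int = 60
    n_iterations: int = 1000
    n_diploid: float | np.ndarray = 300
    n_diploid_x: float | None = None
    x_linked: np.ndarray | None = None
    presence_threshold: float = 0.1
    fitness: GaussianFitness | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.p0 = np.atleast_1d(np.asarray(self.p0, dtype=float))
        if self.s is not None:
            self.s = np.broadcast_to(
                np.asarray(self.s, dtype=float), self.p0.shape).copy()
            if self.s.shape != self.p0.shape:
                raise ValueError("s and p0 must have matching lengths")
        if self.x_linked is not None:
            self.x_linked = np.asarray(self.x_linked, dtype=bool)
            if self.x_linked.shape != self.p0.shape:
                raise ValueError("x_linked mask must match p0 length")
        if self.n_iterations < 1:
            raise ValueError("iterations must be >= 1")

    @property
    def n_alleles(self) -> int:
        return self.p0.size


@dataclass
class ParadigmResult:
    """Per-iteration RFS and Jaccard distributions of one scenario run.

    ``rfs`` has shape (iterations, R): counts of alleles present in exactly
    k = 1..R replicates (class 0 excluded).  ``jaccard`` has shape
    (iterations, R*(R-1)/2).
    """

    scenario: str
    rfs: np.ndarray
    jaccard: np.ndarray
    n_alleles: int

    @property
    def n_replicates(self) -> int:
        return self.rfs.shape[1]

    def rfs_mean(self) -> np.ndarray:
        return self.rfs.mean(axis=0)

    def rfs_ci(self, level: float = 0.95) -> np.ndarray:
        """(2, R) empirical percentile interval of each RFS class."""
        a = (1 - level) / 2 * 100
        return np.percentile(self.rfs, [a, 100 - a], axis=0)

    def sse_distribution(self, observed_rfs: np.ndarray) -> np.ndarray:
        """Per-iteration sum over k of (observed_k - simulated_k)^2."""
        observed_rfs = np.asarray(observed_rfs, dtype=float)
        if observed_rfs.shape != (self.n_replicates,):
            raise ValueError("observed RFS length mismatch")
        return ((observed_rfs[None, :] - self.rfs) ** 2).sum(axis=1)

    def mean_sse(self, observed_rfs: np.ndarray) -> float:
        return float(self.sse_distribution(observed_rfs).mean())


def _rfs_counts(k_per_allele: np.ndarray, n_replicates: int) -> np.ndarray:
    """Counts of alleles by number-of-replicates class 1..R (0 excluded)."""
    out = np.empty(k_per_allele.shape[:-1] + (n_replicates,), dtype=np.int64)
    for c in range(1, n_replicates + 1):
        out[..., c - 1] = (k_per_allele == c).sum(axis=-1)
    return out


def presence_to_result(presence: np.ndarray, scenario: str) -> ParadigmResult:
    """Summarize a boolean presence array (iterations, alleles, replicates)
    into per-iteration RFS and pairwise Jaccard distributions."""
    presence = np.asarray(presence, dtype=bool)
    n_iter, n_alleles, R = presence.shape
    k = presence.sum(axis=2)
    rfs = _rfs_counts(k, R)
    P = presence.transpose(0, 2, 1).astype(np.float64)  # (iter, R, L)
    inter = P @ P.transpose(0, 2, 1)
    sizes = P.sum(axis=2)
    union = sizes[:, :, None] + sizes[:, None, :] - inter
    iu, ju = np.triu_indices(R, k=1)
    inter_p = inter[:, iu, ju]
    union_p = union[:, iu, ju]
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = inter_p / union_p
    jac[union_p == 0] = 1.0  # two empty sets: identical by convention
    return ParadigmResult(scenario=scenario, rfs=rfs, jaccard=jac,
                          n_alleles=n_alleles)


# ---------------------------------------------------------------------------
# frequency-based Wright-Fisher engine


def selection_update(p: np.ndarray | float, s, h=0.5) -> np.ndarray:
    """One deterministic generation of diploid selection.

    p' = [p^2 (1+s) + p q (1+hs)] / [p^2 (1+s) + 2 p q (1+hs) + q^2]
    """
    p = np.asarray(p, dtype=float)
    s = np.asarray(s, dtype=float)
    q = 1.0 - p
    num = p * p * (1.0 + s) + p * q * (1.0 + h * s)
    wbar = p * p * (1.0 + s) + 2.0 * p * q * (1.0 + h * s) + q * q
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / wbar
    return np.where(wbar > 0, out, p)


def wf_simulate(
    p0,
    s=0.0,
    h: float = 0.5,
    n_diploid=300,
    n_generations: int = 60,
    n_replicates: int = 1,
    n_iterations: int = 1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    record: str = "trajectory",
    absorb_stop: bool = False,
):
    """Wright-Fisher forward simulation with selection, no linkage.

    Each generation applies the deterministic selection update and then
    binomial resampling of 2N allele copies; trajectories absorb at 0 and 1.
    ``p0`` and ``s`` broadcast over an allele axis; ``n_diploid`` may be a
    per-replicate vector.  Returns frequencies of shape
    (iterations, alleles, replicates, generations+1), or the final
    frequencies (iterations, alleles, replicates) when ``record='final'``.

    With ``absorb_stop`` the simulation ends early once every trajectory is
    fixed or lost (useful for fixation-probability runs).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    p0 = np.atleast_1d(np.asarray(p0, dtype=float))
    s = np.broadcast_to(np.asarray(s, dtype=float), p0.shape)
    L = p0.size
    n2 = 2 * np.broadcast_to(np.asarray(n_diploid), (n_replicates,)).astype(int)
    if np.any(n2 < 2):
        raise ValueError("n_diploid must be >= 1")
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")

    p = np.broadcast_to(p0[None, :, None],
                        (n_iterations, L, n_replicates)).copy()
    s3 = s[None, :, None]
    n3 = n2[None, None, :]
    if record == "trajectory":
        traj = np.empty((n_iterations, L, n_replicates, n_generations + 1))
        traj[..., 0] = p
    for t in range(1, n_generations + 1):
        p_sel = selection_update(p, s3, h)
        p = rng.binomial(n3, p_sel) / n3
        if record == "trajectory":
            traj[..., t] = p
        if absorb_stop and not np.any((p > 0) & (p < 1)):
            if record == "trajectory":
                traj[..., t:] = p[..., None]
            break
    return traj if record == "trajectory" else p


def sweep_rfs(config: ScenarioConfig) -> ParadigmResult:
    """Scenario: independent selective sweeps (no linkage).

    Every allele is simulated in every replicate with its own starting
    frequency and selection coefficient; X-linked alleles (``x_linked``
    mask) use the X-specific effective size.  Presence in a replicate means
    the final-generation frequency rose by at least ``presence_threshold``.
    """
    if config.s is None:
        raise ValueError("sweep scenario requires selection coefficients")
    rng = np.random.default_rng(config.seed)
    final = np.empty((config.n_iterations, config.n_alleles,
                      config.n_replicates))
    groups = [(np.ones(config.n_alleles, dtype=bool), config.n_diploid)]
    if config.x_linked is not None and config.x_linked.any():
        if config.n_diploid_x is None:
            raise ValueError("x_linked alleles need n_diploid_x")
        groups = [(~config.x_linked, config.n_diploid),
                  (config.x_linked, config.n_diploid_x)]
    for mask, nd in groups:
        if not mask.any():
            continue
        final[:, mask, :] = wf_simulate(
            config.p0[mask], config.s[mask], h=0.5, n_diploid=nd,
            n_generations=config.n_generations,
            n_replicates=config.n_replicates,
            n_iterations=config.n_iterations, rng=rng, record="final")
    presence = (final - config.p0[None, :, None]) >= config.presence_threshold
    return presence_to_result(presence, config.scenario or "sweep_nolink")


# ---------------------------------------------------------------------------
# genetic-redundancy jackknife


def redundancy_jackknife(
    n_selected_per_replicate: Sequence[int],
    n_alleles: int,
    iterations: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ParadigmResult:
    """Delete-d jackknife null of full genetic redundancy.

    Every iteration assigns each replicate a uniform random subset of the
    stated size, drawn without replacement from the ``n_alleles`` pool;
    allele identity carries no information, only the per-replicate counts.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = np.asarray(list(n_selected_per_replicate), dtype=int)
    if np.any(counts > n_alleles):
        raise ValueError("per-replicate count exceeds the allele pool")
    if np.any(counts < 0):
        raise ValueError("negative per-replicate count")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    R = counts.size
    presence = np.zeros((iterations, n_alleles, R), dtype=bool)
    for r in range(R):
        u = rng.random((iterations, n_alleles))
        order = np.argsort(u, axis=1)
        rows = np.repeat(np.arange(iterations), counts[r])
        cols = order[:, :counts[r]].ravel()
        presence[rows, cols, r] = True
    return presence_to_result(presence, "redundancy")


# ---------------------------------------------------------------------------
# quantitative-trait stabilizing selection, no linkage


def qt_simulate(
    p0,
    fitness: GaussianFitness,
    n_diploid: int = 300,
    n_generations: int = 60,
    n_populations: int = 1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    record: str = "final",
    chunk: int = 128,
):
    """Individual-based QT simulation with free recombination.

    Phenotype of an individual is the mean rising-allele dosage over loci,
    ``z = (sum of dosages) / (2 L)`` in [0, 1]; all loci have equal effects.
    Each generation draws genotypes per locus binomially from the current
    frequencies (free recombination / linkage equilibrium), maps phenotypes
    to fitness, samples 2N transmitting parents proportional to fitness and
    transmits one allele per parent per locus (Mendelian).

    Returns final frequencies of shape (populations, L), or trajectories
    (populations, L, generations+1) with ``record='trajectory'``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    p0 = np.atleast_1d(np.asarray(p0, dtype=float))
    L = p0.size
    N = int(n_diploid)
    if N < 2:
        raise ValueError("n_diploid must be >= 2")
    M = int(n_populations)
    p = np.broadcast_to(p0[None, :], (M, L)).copy()
    if record == "trajectory":
        traj = np.empty((M, L, n_generations + 1))
        traj[:, :, 0] = p
    for t in range(1, n_generations + 1):
        for lo in range(0, M, chunk):
            hi = min(lo + chunk, M)
            pc = p[lo:hi]  # (m, L)
            m = hi - lo
            # genotype ~ Binomial(2, p) from one uniform per (ind, locus):
            # g = 2 if u < p^2, 1 if u < 2p - p^2 (correct marginals)
            pb = pc[:, None, :]
            u = rng.random((m, N, L), dtype=np.float32)
            t_any = (2.0 * pb - pb * pb).astype(np.float32)
            t_two = (pb * pb).astype(np.float32)
            any_c = (u < t_any)  # dosage >= 1
            two_c = (u < t_two)  # dosage == 2
            z = (any_c.sum(axis=2, dtype=np.float64)
                 + two_c.sum(axis=2, dtype=np.float64)) / (2.0 * L)  # (m, N)
            w = np.asarray(fitness(z))
            wsum = w.sum(axis=1, keepdims=True)
            # number of gametes contributed by each parent: multinomial(2N, w)
            n_gam = rng.multinomial(2 * N, w / wsum)  # (m, N)
            nf = n_gam.astype(np.float32)[:, None, :]  # (m, 1, N)
            a_cnt = (nf @ two_c.astype(np.float32))[:, 0, :]  # carry for sure
            h_cnt = ((nf @ any_c.astype(np.float32))[:, 0, :]
                     - a_cnt)  # heterozygote gametes transmit w.p. 1/2
            carried = a_cnt + rng.binomial(np.round(h_cnt).astype(np.int64),
                                           0.5)
            p[lo:hi] = carried / (2.0 * N)
        if record == "trajectory":
            traj[:, :, t] = p
    return traj if record == "trajectory" else p


def qt_rfs(config: ScenarioConfig) -> ParadigmResult:
    """Scenario: QT stabilizing selection without linkage.

    1,000-iteration default with 10 replicates; presence per replicate uses
    the same frequency-change threshold as the observed data.
    """
    if config.fitness is None:
        raise ValueError("qt scenario requires a GaussianFitness")
    rng = np.random.default_rng(config.seed)
    M = config.n_iterations * config.n_replicates
    nd = config.n_diploid
    if np.ndim(nd) > 0:
        nd = int(np.round(np.mean(nd)))
    final = qt_simulate(config.p0, config.fitness, n_diploid=int(nd),
                        n_generations=config.n_generations,
                        n_populations=M, rng=rng)  # (M, L)
    final = final.reshape(config.n_iterations, config.n_replicates,
                          config.n_alleles).transpose(0, 2, 1)
    presence = (final - config.p0[None, :, None]) >= config.presence_threshold
    return presence_to_result(presence, config.scenario or "qt_nolink")


# ---------------------------------------------------------------------------
# individual-based engine with linkage (haplotypes + recombination map)


def _chrom_slices(snps) -> list[tuple[str, slice]]:
    out = []
    start = 0
    chroms = snps["chrom"].to_numpy()
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            out.append((chroms[start], slice(start, i)))
            start = i
    return out


def individual_simulate(
    panel: HaplotypePanel,
    selected_idx: Sequence[int],
    s=None,
    mode: str = "sweep",
    fitness: GaussianFitness | None = None,
    qt_scale: str = "standardized",
    n_diploid: int = 300,
    n_generations: int = 60,
    n_replicates: int = 1,
    record_generations: Sequence[int] | None = None,
    record: str = "selected",
    p0=None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Individual-based forward simulation from founder haplotypes.

    Populations of N diploids are founded by drawing founder haplotypes with
    replacement (``p0`` with a single selected locus forces the exact initial
    count of carrier haplotypes).  Each generation, parents are sampled
    proportional to fitness and transmit one recombinant gamete: the
    crossover count per chromosome is Poisson with mean equal to the genetic
    map length in Morgans, positions drawn from the map's inverse cumulative
    function, no interference.

    ``mode='sweep'``: fitness multiplicative over selected loci with genotype
    fitnesses (1, 1+s/2, 1+s).  ``mode='qt'``: phenotype is the dosage sum
    over selected loci, either standardized by its generation-0 mean/sd
    (``qt_scale='standardized'``, matching an optimum stated in SD units) or
    the raw dosage mean in [0, 1] (``qt_scale='dosage'``); fitness is the
    Gaussian function of the phenotype.  No new mutation: standing variation
    only.

    Returns frequencies (replicates, n_recorded_generations, n_loci) where
    loci are the selected loci (``record='selected'``) or all panel SNPs.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if panel.recombination_map is None:
        raise ValueError("panel needs a recombination map")
    sel = np.asarray(list(selected_idx), dtype=int)
    if np.any(sel < 0) or np.any(sel >= panel.n_snps):
        raise ValueError("selected position absent from panel")
    if mode == "sweep":
        if s is None:
            raise ValueError("sweep mode requires s")
        s = np.broadcast_to(np.asarray(s, dtype=float), sel.shape)
    elif mode == "qt":
        if fitness is None:
            raise ValueError("qt mode requires a GaussianFitness")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    N = int(n_diploid)
    if N < 2:
        raise ValueError("n_diploid must be >= 2")
    if record_generations is None:
        record_generations = [n_generations]
    rec_set = {int(g) for g in record_generations}
    rec_sorted = sorted(rec_set)

    H = np.where(panel.alleles < 0, 0, panel.alleles).astype(np.int8)
    chrom_slices = _chrom_slices(panel.snps)
    positions = panel.snps["pos"].to_numpy(float)
    rmap = panel.recombination_map
    chrom_len_M = np.array([rmap.genetic_length(c) for c, _ in chrom_slices])

    n_loci = sel.size if record == "selected" else panel.n_snps
    out = np.empty((n_replicates, len(rec_sorted), n_loci))

    for rep in range(n_replicates):
        pop = _found_population(H, N, sel, p0, rng)
        if mode == "qt" and qt_scale == "standardized":
            d0 = pop[0::2][:, sel] + pop[1::2][:, sel]
            zsum = d0.sum(axis=1).astype(float)
            z_mu, z_sd = zsum.mean(), zsum.std()
            if z_sd == 0:
                z_sd = 1.0
        ri = 0
        if 0 in rec_set:
            out[rep, ri] = _pop_freq(pop, sel, record)
            ri += 1
        for t in range(1, n_generations + 1):
            dos = pop[0::2][:, sel] + pop[1::2][:, sel]
            if mode == "sweep":
                w = np.prod(1.0 + s[None, :] * dos / 2.0, axis=1)
            else:
                zsum = dos.sum(axis=1).astype(float)
                if qt_scale == "standardized":
                    z = (zsum - z_mu) / z_sd
                else:
                    z = zsum / (2.0 * sel.size)
                w = np.asarray(fitness(z))
            pop = _next_generation(pop, w, chrom_slices, chrom_len_M,
                                   positions, rmap, rng)
            if t in rec_set:
                out[rep, ri] = _pop_freq(pop, sel, record)
                ri += 1
    return out


def _found_population(H: np.ndarray, N: int, sel: np.ndarray, p0,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw 2N founding haplotypes with replacement.  With ``p0`` and one
    selected locus, carrier/non-carrier counts are fixed to round(2N p0)."""
    nh = H.shape[0]
    if p0 is None:
        idx = rng.integers(0, nh, size=2 * N)
    else:
        p0 = np.atleast_1d(np.asarray(p0, dtype=float))
        if sel.size != 1 or p0.size != 1:
            raise ValueError("exact-frequency founding supports one selected "
                             "locus; pass p0=None for multi-locus panels")
        carriers = np.nonzero(H[:, sel[0]] == 1)[0]
        others = np.nonzero(H[:, sel[0]] == 0)[0]
        k = int(round(2 * N * float(p0[0])))
        if carriers.size == 0 or others.size == 0:
            raise ValueError("selected locus monomorphic in panel")
        idx = np.concatenate([rng.choice(carriers, size=k, replace=True),
                              rng.choice(others, size=2 * N - k,
                                         replace=True)])
        rng.shuffle(idx)
    return H[idx].copy()


def _pop_freq(pop: np.ndarray, sel: np.ndarray, record: str) -> np.ndarray:
    if record == "selected":
        return pop[:, sel].mean(axis=0)
    return pop.mean(axis=0)


def _next_generation(pop, w, chrom_slices, chrom_len_M, positions, rmap,
                     rng) -> np.ndarray:
    """Sample 2N gametes from parents chosen proportional to fitness.

    Chromosomes assort independently: each gamete picks a random parental
    haplotype per chromosome and switches at Poisson-count crossovers."""
    N2 = pop.shape[0]
    N = N2 // 2
    n_chrom = len(chrom_slices)
    cw = np.cumsum(w)
    parents = np.searchsorted(cw, rng.random(N2) * cw[-1])
    parents = np.minimum(parents, N - 1)
    hstart = rng.integers(0, 2, size=(N2, n_chrom))
    k_x = rng.poisson(chrom_len_M[None, :], size=(N2, n_chrom))
    new = np.empty_like(pop)
    for ci, (chrom, sl) in enumerate(chrom_slices):
        rows = 2 * parents + hstart[:, ci]
        recomb = np.nonzero(k_x[:, ci] > 0)[0]
        plain = k_x[:, ci] == 0
        new[plain, sl] = pop[rows[plain], sl]
        if recomb.size == 0:
            continue
        ks = k_x[recomb, ci]
        xs_all = rmap.sample_crossovers(chrom, int(ks.sum()), rng)
        bounds = np.concatenate([[0], np.cumsum(ks)])
        pos_c = positions[sl]
        for gi, g in enumerate(recomb):
            pa = parents[g]
            xs = np.sort(xs_all[bounds[gi]:bounds[gi + 1]])
            parity = np.searchsorted(xs, pos_c) % 2
            use1 = (parity + hstart[g, ci]) % 2 == 1
            new[g, sl] = np.where(use1, pop[2 * pa + 1, sl], pop[2 * pa, sl])
    return new
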