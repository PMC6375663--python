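"""Selected-haplotype-block reconstruction by trajectory clustering.

With few recombination events in 60 generations, selected variants ride
large haplotype blocks, so the marker SNPs of one block share essentially
one frequency trajectory across replicates and time points.  Candidate-SNP
frequencies are arcsine-square-root transformed, z-standardized per SNP,
and clustered hierarchically (average linkage on the Euclidean distance
``d = sqrt(2 (1 - r))`` of the pairwise Pearson correlation) in 1 Mb
sliding windows with 500 kb steps.  Two rounds are run: a stringent round
at mean pairwise r >= 0.75 groups tightly linked markers, and a relaxed
round at r >= 0.35 over the surviving SNPs joins adjacent clusters whose
trajectories were decoupled by recombination.  Clusters from overlapping
windows are merged when they share at least five SNPs; only clusters with
more than 20 SNPs are retained.  The final round-2 clusters are the
reconstructed blocks; round-1 sub-clusters are kept for core-region
analyses.  Blocks are validated against phased haplotype panels by an
80%-identity rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .io import AlleleCountTensor, HaplotypePanel, align_panel
from .selection import SelectedAllele

__all__ = [
    "TrajectoryMatrix",
    "Cluster",
    "HaplotypeBlock",
    "polarize_rising",
    "select_block_input",
    "build_trajectory_matrix",
    "cluster_window",
    "merge_clusters",
    "reconstruct_blocks",
    "validate_blocks",
    "to_selected_alleles",
]


# ---------------------------------------------------------------------------
# polarization and input selection


def polarize_rising(tensor: AlleleCountTensor) -> AlleleCountTensor:
    """Orient every SNP so the rising allele is the one whose mean frequency
    change across replicates (first to last generation) is positive.

    Exact ties pick the lexicographically smaller nucleotide and are counted
    in ``meta['polarization_ties']``.  Idempotent.
    """
    freq = tensor.frequency()
    delta = np.nanmean(freq[:, :, -1] - freq[:, :, 0], axis=1)
    flip = delta < 0
    tie = delta == 0
    rising = tensor.snps["rising"].to_numpy().copy()
    other = tensor.snps["other"].to_numpy().copy()
    # ties: smaller nucleotide becomes the rising allele
    flip = flip | (tie & (other < rising))
    rising_count = tensor.rising_count.copy()
    rising_count[flip] = tensor.coverage[flip] - rising_count[flip]
    snps = tensor.snps.copy()
    snps.loc[flip, "rising"] = other[flip]
    snps.loc[flip, "other"] = rising[flip]
    meta = dict(tensor.meta)
    meta["polarization_ties"] = int(tie.sum())
    return AlleleCountTensor(snps=snps, replicates=list(tensor.replicates),
                             generations=tensor.generations.copy(),
                             rising_count=rising_count,
                             coverage=tensor.coverage.copy(), meta=meta)


def _max_rise(freq: np.ndarray) -> np.ndarray:
    """Max over ordered time-point pairs t1 < t2 of p(t2) - p(t1), per
    (SNP, replicate)."""
    run_min = np.fmin.accumulate(freq, axis=2)
    rise = freq[:, :, 1:] - run_min[:, :, :-1]
    return np.nanmax(rise, axis=2)


def select_block_input(
    candidates: pd.DataFrame,
    tensor: AlleleCountTensor,
    q_threshold: float = 0.05,
    rise_threshold: float = 0.2,
    min_replicates: int = 2,
) -> np.ndarray:
    """SNP indices entering block reconstruction.

    CMH candidates must additionally rise by at least ``rise_threshold``
    between some pair of time points in at least ``min_replicates``
    replicates; Fisher candidates enter with no rise rule.  Returns sorted
    indices into the tensor; empty output is a warning.
    """
    if len(candidates) != tensor.n_snps:
        raise ValueError("candidate table and tensor row counts differ")
    cmh_q = candidates["cmh_q"].to_numpy(dtype=float)
    cmh_cand = np.nan_to_num(cmh_q, nan=1.0) <= q_threshold
    freq = tensor.frequency()
    n_rising = (_max_rise(freq) >= rise_threshold).sum(axis=1)
    cmh_keep = cmh_cand & (n_rising >= min_replicates)

    fisher_cols = [c for c in candidates.columns
                   if c.startswith("fisher_q_")]
    fisher_keep = np.zeros(tensor.n_snps, dtype=bool)
    for col in fisher_cols:
        q = candidates[col].to_numpy(dtype=float)
        fisher_keep |= np.nan_to_num(q, nan=1.0) <= q_threshold
    keep = np.nonzero(cmh_keep | fisher_keep)[0]
    if keep.size == 0:
        warnings.warn("no SNPs selected for block reconstruction",
                      stacklevel=2)
    return keep


# ---------------------------------------------------------------------------
# trajectory matrix


@dataclass
class TrajectoryMatrix:
    """Rows = candidate SNPs, columns = (replicate, generation) pairs in
    fixed order; entries are z-standardized arcsine-sqrt frequencies."""

    values: np.ndarray
    snp_idx: np.ndarray  # tensor row of each matrix row
    columns: list
    n_dropped_constant: int = 0


def build_trajectory_matrix(tensor: AlleleCountTensor,
                            snp_idx: np.ndarray) -> TrajectoryMatrix:
    """Arcsine-sqrt transform and per-row z-standardization.

    p = 0 maps to 0 and p = 1 to pi/2 before standardization; masked cells
    (zero coverage) are excluded from the row moments; rows with zero
    variance are dropped and counted.
    """
    snp_idx = np.asarray(snp_idx, dtype=int)
    freq = tensor.frequency()[snp_idx]  # (n, R, G)
    n, R, G = freq.shape
    y = np.arcsin(np.sqrt(freq)).reshape(n, R * G)
    mu = np.nanmean(y, axis=1, keepdims=True)
    sd = np.nanstd(y, axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (y - mu) / sd
    columns = [(rep, int(gen)) for rep in tensor.replicates
               for gen in tensor.generations]
    return TrajectoryMatrix(values=z[keep], snp_idx=snp_idx[keep],
                            columns=columns,
                            n_dropped_constant=int((~keep).sum()))


def _pairwise_r(X: np.ndarray, min_shared: int = 30) -> np.ndarray:
    """Pairwise Pearson correlation over columns; pairwise-complete for
    masked cells, with r = 0 for pairs sharing fewer than ``min_shared``
    columns."""
    if not np.isnan(X).any():
        r = np.corrcoef(X)
        return np.atleast_2d(r)
    mask = np.isfinite(X)
    Xf = np.nan_to_num(X, nan=0.0)
    n_shared = mask.astype(float) @ mask.T.astype(float)
    sx = Xf @ mask.T.astype(float)
    sy = mask.astype(float) @ Xf.T
    sxx = (Xf * Xf) @ mask.T.astype(float)
    syy = mask.astype(float) @ (Xf * Xf).T
    sxy = Xf @ Xf.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n_shared
        vx = sxx - sx * sx / n_shared
        vy = syy - sy * sy / n_shared
        r = cov / np.sqrt(vx * vy)
    r = np.where(n_shared >= min_shared, r, 0.0)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


# ---------------------------------------------------------------------------
# clustering


@dataclass
class Cluster:
    members: np.ndarray  # global tensor SNP rows
    mean_r: float
    windows: set = field(default_factory=set)


def _cut_by_mean_r(Z: np.ndarray, R: np.ndarray,
                   r_min: float) -> list[np.ndarray]:
    """Cut an agglomerative tree at the largest subtrees whose mean pairwise
    correlation meets ``r_min``; singletons are discarded."""
    n = R.shape[0]
    members: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n)}
    sum_r: dict[int, float] = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for k, (a, b, _, _) in enumerate(Z):
        a, b = int(a), int(b)
        node = n + k
        ma, mb = members[a], members[b]
        cross = float(R[np.ix_(ma, mb)].sum())
        members[node] = np.concatenate([ma, mb])
        sum_r[node] = sum_r[a] + sum_r[b] + cross
        children[node] = (a, b)
    out = []
    stack = [n + len(Z) - 1] if len(Z) else []
    while stack:
        node = stack.pop()
        m = members[node]
        if m.size < 2:
            continue
        npairs = m.size * (m.size - 1) / 2
        if sum_r[node] / npairs >= r_min:
            m = _prune_members(m, R, r_min)
            if m is not None:
                out.append(np.sort(m))
        else:
            stack.extend(children[node])
    return out


def _prune_members(m: np.ndarray, R: np.ndarray,
                   r_min: float) -> np.ndarray | None:
    """Drop members whose average correlation to the rest of the cluster
    falls below the threshold (worst first), so a tight cluster cannot
    absorb loosely attached SNPs through its high internal correlation."""
    while m.size >= 2:
        sub = R[np.ix_(m, m)]
        avg = (sub.sum(axis=1) - 1.0) / (m.size - 1)
        worst = int(np.argmin(avg))
        if avg[worst] >= r_min:
            return m
        m = np.delete(m, worst)
    return None


def cluster_window(X: np.ndarray, r_min: float,
                   min_shared_columns: int = 30) -> list[np.ndarray]:
    """Cluster the rows of one window's trajectory matrix.

    Pairwise Pearson r -> distance d = sqrt(2 (1 - r)) -> average-linkage
    tree -> cut at the largest subtrees with mean pairwise r >= ``r_min``.
    Returns lists of local row indices (singletons discarded).
    """
    if X.shape[0] < 2:
        return []
    R = _pairwise_r(X, min_shared=min_shared_columns)
    d = np.sqrt(np.maximum(2.0 * (1.0 - R), 0.0))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    Z = linkage(squareform(d, checks=False), method="average")
    return _cut_by_mean_r(Z, R, r_min)


def merge_clusters(clusters: list[Cluster], min_shared: int = 5,
                   min_members: int = 21) -> list[Cluster]:
    """Merge clusters from overlapping windows sharing >= ``min_shared``
    SNPs (transitive closure via union-find), then retain only merged
    clusters with at least ``min_members`` members (the "more than 20
    SNPs" rule)."""
    n = len(clusters)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    sets = [set(c.members.tolist()) for c in clusters]
    for i in range(n):
        for j in range(i + 1, n):
            if len(sets[i] & sets[j]) >= min_shared:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged = []
    for idxs in groups.values():
        mem = sorted(set().union(*(sets[i] for i in idxs)))
        if len(mem) < min_members:
            continue
        windows = set().union(*(clusters[i].windows for i in idxs))
        merged.append(Cluster(members=np.array(mem, dtype=int),
                              mean_r=np.nan, windows=windows))
    return merged


def _windows(positions: np.ndarray, window_bp: int, step_bp: int):
    """Half-open [start, start + window) windows anchored at coordinate 1."""
    if positions.size == 0:
        return
    last = int(positions.max())
    start = 1
    while start <= last:
        yield start, start + window_bp
        start += step_bp


def _cluster_round(
    tm: TrajectoryMatrix,
    snps: pd.DataFrame,
    row_subset: np.ndarray,
    r_min: float,
    window_bp: int,
    step_bp: int,
    min_window_snps: int,
    min_shared: int,
    min_members: int,
) -> list[Cluster]:
    """One round of windowed clustering + cross-window merging + dedup."""
    rows = row_subset
    chroms = snps["chrom"].to_numpy()[tm.snp_idx[rows]]
    pos = snps["pos"].to_numpy()[tm.snp_idx[rows]]
    raw: list[Cluster] = []
    wid = 0
    for chrom in pd.unique(chroms):
        on_chrom = np.nonzero(chroms == chrom)[0]
        cpos = pos[on_chrom]
        for wstart, wend in _windows(cpos, window_bp, step_bp):
            local = on_chrom[(cpos >= wstart) & (cpos < wend)]
            wid += 1
            if local.size < min_window_snps:
                continue
            X = tm.values[rows[local]]
            for grp in cluster_window(X, r_min):
                raw.append(Cluster(members=rows[local[grp]],
                                   mean_r=np.nan, windows={wid}))
    merged = merge_clusters(raw, min_shared=min_shared,
                            min_members=min_members)
    return _deduplicate(merged, tm)


def _deduplicate(clusters: list[Cluster],
                 tm: TrajectoryMatrix) -> list[Cluster]:
    """A SNP left in several clusters after merging goes to the cluster
    with the higher mean correlation to it (deterministic)."""
    owner: dict[int, int] = {}
    claim: dict[int, float] = {}
    row_of = {r: i for i, r in enumerate(range(tm.values.shape[0]))}
    for ci, c in enumerate(clusters):
        for m in c.members:
            if m not in owner:
                owner[m] = ci
                continue
            # contested: compare mean r to each cluster's members
            for cand in (owner[m], ci):
                if (m, cand) not in claim:
                    others = np.setdiff1d(clusters[cand].members, [m])
                    x = tm.values[m][None, :]
                    r = _pairwise_r(np.vstack([x, tm.values[others]]))[0, 1:]
                    claim[(m, cand)] = float(r.mean())
            if claim[(m, ci)] > claim[(m, owner[m])]:
                owner[m] = ci
    out = []
    for ci, c in enumerate(clusters):
        mem = np.array(sorted(m for m in c.members if owner[m] == ci),
                       dtype=int)
        if mem.size:
            out.append(Cluster(members=mem, mean_r=_mean_pairwise_r(tm, mem),
                               windows=c.windows))
    return out


def _mean_pairwise_r(tm: TrajectoryMatrix, rows: np.ndarray) -> float:
    if rows.size < 2:
        return np.nan
    R = _pairwise_r(tm.values[rows])
    iu = np.triu_indices(rows.size, k=1)
    return float(R[iu].mean())


# ---------------------------------------------------------------------------
# blocks


@dataclass
class HaplotypeBlock:
    """A reconstructed selected haplotype block ("selected allele")."""

    block_id: int
    marker_idx: np.ndarray  # tensor SNP rows, sorted by position
    snps: pd.DataFrame
    chrom: str
    start: int
    end: int
    mean_r: float
    trajectories: np.ndarray  # (R, G) median marker frequency
    generations: np.ndarray
    sub_clusters: list = field(default_factory=list)

    @property
    def size_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def n_markers(self) -> int:
        return len(self.marker_idx)


def reconstruct_blocks(
    tensor: AlleleCountTensor,
    candidate_idx: np.ndarray,
    r_round1: float = 0.75,
    r_round2: float = 0.35,
    window_bp: int = 1_000_000,
    step_bp: int = 500_000,
    min_window_snps: int = 20,
    min_cluster_snps: int = 21,
    min_shared: int = 5,
) -> list[HaplotypeBlock]:
    """Two-stage reconstruction of selected haplotype blocks.

    Round 1 clusters candidate-SNP trajectories at mean pairwise r >= 0.75;
    round 2 re-clusters all SNPs surviving round 1 at r >= 0.35 with
    identical windowing and merge rules.  Round-2 clusters become the final
    blocks; member SNPs are the block markers and the per-replicate block
    frequency is the median over markers at each (replicate, generation).
    Round-1 clusters nested in a block are attached as its sub-clusters.
    """
    # canonical sort makes reconstruction invariant to SNP input order
    tm = build_trajectory_matrix(
        tensor, np.unique(np.asarray(candidate_idx, int)))
    if tm.values.shape[0] == 0:
        return []
    all_rows = np.arange(tm.values.shape[0])
    round1 = _cluster_round(tm, tensor.snps, all_rows, r_round1, window_bp,
                            step_bp, min_window_snps, min_shared,
                            min_cluster_snps)
    if not round1:
        return []
    surviving = np.sort(np.concatenate([c.members for c in round1]))
    round2 = _cluster_round(tm, tensor.snps, surviving, r_round2, window_bp,
                            step_bp, min_window_snps, min_shared,
                            min_cluster_snps)

    freq = tensor.frequency()
    blocks = []
    for bi, c in enumerate(sorted(round2,
                                  key=lambda c: (tensor.snps["chrom"]
                                                 .iloc[tm.snp_idx[c.members[0]]],
                                                 tensor.snps["pos"]
                                                 .iloc[tm.snp_idx[c.members[0]]]))):
        snp_rows = np.sort(tm.snp_idx[c.members])
        sub = tensor.snps.iloc[snp_rows]
        traj = np.nanmedian(freq[snp_rows], axis=0)
        member_set = set(c.members.tolist())
        subs = []
        for r1c in round1:
            inter = np.array(sorted(set(r1c.members) & member_set), int)
            if inter.size >= 2:
                rows = np.sort(tm.snp_idx[inter])
                subs.append((rows, np.nanmedian(freq[rows], axis=0)))
        blocks.append(HaplotypeBlock(
            block_id=bi, marker_idx=snp_rows, snps=sub.reset_index(drop=True),
            chrom=str(sub["chrom"].iloc[0]), start=int(sub["pos"].min()),
            end=int(sub["pos"].max()), mean_r=c.mean_r, trajectories=traj,
            generations=tensor.generations.copy(), sub_clusters=subs))
    return blocks


# ---------------------------------------------------------------------------
# validation against phased haplotypes


def validate_blocks(
    blocks: list[HaplotypeBlock],
    panel: HaplotypePanel,
    max_mismatch: float = 0.20,
) -> pd.DataFrame:
    """Count phased haplotypes containing each reconstructed block.

    A haplotype contains a block when its mismatched-plus-missing fraction
    over the block's markers is at most ``max_mismatch`` (>= 80% identity
    by default); markers absent from the panel count as missing.  Blocks
    with no marker present in the panel are flagged unvalidatable.
    """
    rows = []
    for b in blocks:
        cols = align_panel(panel, b.snps)
        present = cols >= 0
        n = b.n_markers
        if not present.any():
            rows.append({"block_id": b.block_id, "n_matching": 0,
                         "n_markers": n, "unvalidatable": True})
            continue
        states = panel.alleles[:, cols[present]]  # (H, n_present)
        mismatch = (states == 0).sum(axis=1)
        missing = (states == -1).sum(axis=1) + (n - int(present.sum()))
        frac = (mismatch + missing) / n
        rows.append({"block_id": b.block_id,
                     "n_matching": int((frac <= max_mismatch).sum()),
                     "n_markers": n, "unvalidatable": False})
    return pd.DataFrame(rows)


def to_selected_alleles(blocks: list[HaplotypeBlock],
                        tensor: AlleleCountTensor) -> list[SelectedAllele]:
    """Wrap reconstructed blocks as selected alleles for presence calling
    and s inference."""
    cov = float(np.mean(tensor.coverage)) if tensor.n_snps else None
    return [SelectedAllele(allele_id=b.block_id,
                           trajectories=b.trajectories,
                           generations=b.generations,
                           sub_clusters=b.sub_clusters,
                           coverage=cov)
            for b in blocks]
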