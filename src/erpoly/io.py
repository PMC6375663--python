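"""Pool-Seq file formats and the allele-count tensor.

The central observable of a replicated evolve-and-resequence (E&R) experiment
is, for every SNP, the count of the rising allele and the total usable
coverage in each (replicate, generation) sample.  This module reads and
writes the PoPoolation2 "sync" format (tab-separated ``A:T:C:G:N:del``
count 6-tuples, one column per population sample), a plain haplotype-matrix
TSV for phased founder/evolved haplotypes, a design table mapping sync
columns to (replicate, generation), and a piecewise-constant recombination
map, and assembles everything into an :class:`AlleleCountTensor`.

Conventions: coordinates are 1-based inclusive (sync convention); coverage
of a SNP is the sum of its two retained allele counts (``N`` and ``del``
counts never enter coverage); generations need not be equally spaced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyncParseError",
    "SyncRecord",
    "AlleleCountTensor",
    "DesignTable",
    "HaplotypePanel",
    "RecombinationMap",
    "parse_sync",
    "assemble_tensor",
    "read_sync",
    "write_sync",
    "read_haplotypes",
    "write_haplotypes",
    "read_design",
    "write_design",
    "merge_arms",
]

#: allele order of a sync count tuple
SYNC_ALLELES = ("A", "T", "C", "G", "N", "del")
_NUC = ("A", "T", "C", "G")


class SyncParseError(ValueError):
    """Malformed sync input; carries the 1-based line and field number."""

    def __init__(self, message: str, line: int, fld: int | None = None):
        self.line = line
        self.field = fld
        where = f"line {line}" + ("" if fld is None else f", field {fld}")
        super().__init__(f"{message} ({where})")


@dataclass
class SyncRecord:
    """One sync line: a SNP with per-population A/T/C/G/N/del counts."""

    chrom: str
    pos: int  # 1-based
    ref: str
    counts: np.ndarray  # (n_populations, 6) non-negative ints

    @property
    def n_populations(self) -> int:
        return self.counts.shape[0]


def parse_sync(lines: Iterable[str]) -> list[SyncRecord]:
    """Parse a sync line stream into records, preserving counts exactly.

    Raises :class:`SyncParseError` naming the offending line and field for
    non-integer counts or count tuples whose arity is not 6.
    """
    records: list[SyncRecord] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise SyncParseError("expected chrom, pos, ref and >=1 count column",
                                 lineno)
        chrom, pos_s, ref = parts[0], parts[1], parts[2]
        try:
            pos = int(pos_s)
        except ValueError:
            raise SyncParseError(f"non-integer position {pos_s!r}", lineno) from None
        counts = np.empty((len(parts) - 3, 6), dtype=np.int64)
        for j, tup in enumerate(parts[3:], start=1):
            bits = tup.split(":")
            if len(bits) != 6:
                raise SyncParseError(
                    f"count tuple {tup!r} has {len(bits)} fields, expected 6",
                    lineno, j)
            for k, b in enumerate(bits):
                try:
                    v = int(b)
                except ValueError:
                    raise SyncParseError(f"non-integer count {b!r}", lineno,
                                         j) from None
                if v < 0:
                    raise SyncParseError(f"negative count {v}", lineno, j)
                counts[j - 1, k] = v
        records.append(SyncRecord(chrom, pos, ref, counts))
    return records


def read_sync(path: str | Path) -> list[SyncRecord]:
    with open(path) as fh:
        return parse_sync(fh)


# ---------------------------------------------------------------------------
# design table


@dataclass
class DesignTable:
    """Maps (sync file, column index) to (replicate label, generation).

    Column indices are 0-based over the count columns of the file.  Each
    (replicate, generation) pair may appear at most once.
    """

    rows: pd.DataFrame  # columns: file, column, replicate, generation

    def __post_init__(self) -> None:
        req = {"file", "column", "replicate", "generation"}
        missing = req - set(self.rows.columns)
        if missing:
            raise ValueError(f"design table missing columns {sorted(missing)}")
        dup = self.rows.duplicated(subset=["replicate", "generation"])
        if dup.any():
            bad = self.rows.loc[dup, ["replicate", "generation"]]
            raise ValueError(
                f"duplicate (replicate, generation) cells in design: "
                f"{bad.to_records(index=False).tolist()}")

    @property
    def replicates(self) -> list:
        return sorted(self.rows["replicate"].unique().tolist())

    @property
    def generations(self) -> list[int]:
        return sorted(int(g) for g in self.rows["generation"].unique())


def read_design(path: str | Path) -> DesignTable:
    return DesignTable(pd.read_csv(path, sep="\t"))


def write_design(design: DesignTable, path: str | Path) -> None:
    design.rows.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# allele-count tensor


@dataclass
class AlleleCountTensor:
    """Rising-allele counts and coverages over (SNP, replicate, generation).

    ``snps`` holds one row per SNP with columns ``chrom``, ``pos``,
    ``ref``, ``rising``, ``other`` (the two retained alleles, ``rising``
    being the provisional or polarized rising allele).  ``rising_count``
    and ``coverage`` are integer arrays of shape (S, R, G); frequencies are
    ``rising_count / coverage`` and are undefined (NaN) where coverage is 0.
    """

    snps: pd.DataFrame
    replicates: list
    generations: np.ndarray
    rising_count: np.ndarray
    coverage: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=int)
        if not np.all(np.diff(self.generations) > 0):
            raise ValueError("generations must be strictly increasing")
        S, R, G = self.rising_count.shape
        if self.coverage.shape != (S, R, G):
            raise ValueError("rising_count and coverage shapes differ")
        if len(self.snps) != S or len(self.replicates) != R or len(
                self.generations) != G:
            raise ValueError("axis labels inconsistent with array shapes")
        if np.any(self.rising_count < 0) or np.any(
                self.rising_count > self.coverage):
            raise ValueError("require 0 <= rising_count <= coverage")

    @property
    def n_snps(self) -> int:
        return self.rising_count.shape[0]

    def frequency(self) -> np.ndarray:
        """Rising-allele frequency, NaN where coverage is zero."""
        cov = self.coverage.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.rising_count / cov
        f[cov == 0] = np.nan
        return f

    def gen_index(self, generation: int) -> int:
        idx = np.nonzero(self.generations == generation)[0]
        if idx.size == 0:
            raise KeyError(f"generation {generation} not in tensor")
        return int(idx[0])

    def subset(self, snp_mask: np.ndarray) -> "AlleleCountTensor":
        snp_mask = np.asarray(snp_mask)
        return AlleleCountTensor(
            snps=self.snps.loc[snp_mask].reset_index(drop=True)
            if snp_mask.dtype == bool else
            self.snps.iloc[snp_mask].reset_index(drop=True),
            replicates=list(self.replicates),
            generations=self.generations.copy(),
            rising_count=self.rising_count[snp_mask].copy(),
            coverage=self.coverage[snp_mask].copy(),
            meta=dict(self.meta),
        )

    def sorted_by_position(self) -> "AlleleCountTensor":
        order = np.lexsort((self.snps["pos"].to_numpy(),
                            self.snps["chrom"].to_numpy()))
        return self.subset(order)


def _retain_biallelic(total_counts: np.ndarray, ref: str,
                      minor_threshold: int) -> tuple[int, int] | None:
    """Pick the two retained allele indices for one SNP, or None to drop.

    ``total_counts`` are the 4 nucleotide totals summed over every sample.
    Alleles with total count above ``minor_threshold`` are considered real;
    more than two real alleles disqualifies the SNP.  The two retained
    alleles are the two highest-count ones, with the reference base kept
    when tied.
    """
    above = np.nonzero(total_counts > minor_threshold)[0]
    if above.size > 2:
        return None
    order = np.argsort(-total_counts, kind="stable")
    a1, a2 = int(order[0]), int(order[1])
    ref_i = _NUC.index(ref) if ref in _NUC else -1
    # keep the reference among the retained pair when counts allow
    if ref_i >= 0 and ref_i not in (a1, a2) and \
            total_counts[ref_i] == total_counts[a2]:
        a2 = ref_i
    return a1, a2


def assemble_tensor(
    records_by_file: Mapping[str, Sequence[SyncRecord]],
    design: DesignTable,
    minor_threshold: int = 0,
) -> tuple[AlleleCountTensor, dict]:
    """Assemble the allele-count tensor from per-file sync records.

    Every (replicate, generation) cell of the design must be covered by a
    (file, column) entry whose file is present in ``records_by_file``.  Each
    SNP is reduced to its two highest-count alleles over all samples;
    SNPs with more than two alleles above ``minor_threshold`` total reads
    are dropped and counted in the returned run report.  Coverage is the sum
    of the two retained allele counts; the provisional rising allele is the
    retained non-reference allele (re-polarized downstream).
    """
    reps = design.replicates
    gens = design.generations
    rep_i = {r: i for i, r in enumerate(reps)}
    gen_i = {g: i for i, g in enumerate(gens)}

    # (file, column) -> (rep index, gen index); check completeness
    cellmap: dict[tuple[str, int], tuple[int, int]] = {}
    seen_cells = set()
    for row in design.rows.itertuples(index=False):
        cellmap[(row.file, int(row.column))] = (rep_i[row.replicate],
                                                gen_i[int(row.generation)])
        seen_cells.add((row.replicate, int(row.generation)))
    for r in reps:
        for g in gens:
            if (r, g) not in seen_cells:
                raise ValueError(f"design missing cell (replicate={r!r}, "
                                 f"generation={g})")
    for fname in {f for f, _ in cellmap}:
        if fname not in records_by_file:
            raise ValueError(f"no sync records supplied for file {fname!r}")

    # consistent SNP list across files
    key_lists = {}
    for fname, recs in records_by_file.items():
        key_lists[fname] = [(r.chrom, r.pos, r.ref) for r in recs]
    first = next(iter(key_lists.values()))
    for fname, keys in key_lists.items():
        if keys != first:
            raise ValueError(f"SNP list of {fname!r} differs from the other "
                             "sync files")

    S, R, G = len(first), len(reps), len(gens)
    nuc_counts = np.zeros((S, R, G, 4), dtype=np.int64)
    for (fname, col), (ri, gi) in cellmap.items():
        recs = records_by_file[fname]
        for si, rec in enumerate(recs):
            if col >= rec.n_populations:
                raise ValueError(f"file {fname!r} has no column {col}")
            nuc_counts[si, ri, gi, :] = rec.counts[col, :4]

    totals = nuc_counts.sum(axis=(1, 2))  # (S, 4)
    keep_rows, rising_idx, other_idx, dropped = [], [], [], 0
    refs = [k[2] for k in first]
    for si in range(S):
        pick = _retain_biallelic(totals[si], refs[si], minor_threshold)
        if pick is None:
            dropped += 1
            continue
        a1, a2 = pick
        ref_i = _NUC.index(refs[si]) if refs[si] in _NUC else -1
        if a2 == ref_i:
            ris, oth = a1, a2
        elif a1 == ref_i:
            ris, oth = a2, a1
        else:  # reference not retained: major is "rising" provisionally
            ris, oth = a1, a2
        keep_rows.append(si)
        rising_idx.append(ris)
        other_idx.append(oth)

    keep = np.array(keep_rows, dtype=int)
    ris = np.array(rising_idx, dtype=int)
    oth = np.array(other_idx, dtype=int)
    kept_counts = nuc_counts[keep]  # (S', R, G, 4)
    rising_count = np.take_along_axis(
        kept_counts, ris[:, None, None, None], axis=3)[..., 0]
    other_count = np.take_along_axis(
        kept_counts, oth[:, None, None, None], axis=3)[..., 0]
    snps = pd.DataFrame({
        "chrom": [first[i][0] for i in keep],
        "pos": [first[i][1] for i in keep],
        "ref": [first[i][2] for i in keep],
        "rising": [_NUC[i] for i in ris],
        "other": [_NUC[i] for i in oth],
    })
    tensor = AlleleCountTensor(
        snps=snps,
        replicates=reps,
        generations=np.array(gens),
        rising_count=rising_count,
        coverage=rising_count + other_count,
    ).sorted_by_position()
    report = {
        "n_input_snps": S,
        "n_retained_snps": int(keep.size),
        "n_dropped_multiallelic": dropped,
        "minor_threshold": minor_threshold,
    }
    return tensor, report


def write_sync(tensor: AlleleCountTensor, directory: str | Path,
               prefix: str = "experiment",
               run_report: dict | None = None) -> tuple[list[Path], Path]:
    """Write one sync file per generation (R columns each) plus a design
    table and a sidecar JSON run report.  Counts round-trip bit-exactly
    through :func:`read_sync` + :func:`assemble_tensor`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    design_rows = []
    other_count = tensor.coverage - tensor.rising_count
    for gi, gen in enumerate(tensor.generations):
        path = directory / f"{prefix}_F{int(gen)}.sync"
        with open(path, "w") as fh:
            for si in range(tensor.n_snps):
                row = tensor.snps.iloc[si]
                cols = []
                for ri in range(len(tensor.replicates)):
                    c = [0] * 6
                    c[SYNC_ALLELES.index(row["rising"])] = int(
                        tensor.rising_count[si, ri, gi])
                    c[SYNC_ALLELES.index(row["other"])] = int(
                        other_count[si, ri, gi])
                    cols.append(":".join(str(v) for v in c))
                fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{row['ref']}\t"
                         + "\t".join(cols) + "\n")
        paths.append(path)
        for ri, rep in enumerate(tensor.replicates):
            design_rows.append({"file": path.name, "column": ri,
                                "replicate": rep, "generation": int(gen)})
    design_path = directory / f"{prefix}_design.tsv"
    pd.DataFrame(design_rows).to_csv(design_path, sep="\t", index=False)
    report = dict(run_report or {})
    report.setdefault("n_snps", tensor.n_snps)
    report.setdefault("replicates", list(map(str, tensor.replicates)))
    report.setdefault("generations", [int(g) for g in tensor.generations])
    with open(directory / f"{prefix}_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return paths, design_path


def read_experiment(directory: str | Path, prefix: str = "experiment",
                    minor_threshold: int = 0) -> tuple[AlleleCountTensor, dict]:
    """Re-assemble a tensor written by :func:`write_sync`."""
    directory = Path(directory)
    design = read_design(directory / f"{prefix}_design.tsv")
    records = {f: read_sync(directory / f)
               for f in design.rows["file"].unique()}
    return assemble_tensor(records, design, minor_threshold=minor_threshold)


# ---------------------------------------------------------------------------
# haplotype panel


@dataclass
class RecombinationMap:
    """Piecewise-constant recombination rate (cM/Mb) per physical window.

    ``table`` has columns ``chrom``, ``start``, ``end`` (1-based inclusive
    physical bp) and ``rate`` (cM/Mb).  Genetic positions are the cumulative
    integral of the rate; crossover positions are drawn by inverting the
    cumulative genetic map (no interference).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end", "rate"}
        if req - set(self.table.columns):
            raise ValueError(f"map needs columns {sorted(req)}")
        if (self.table["rate"] < 0).any():
            raise ValueError("negative recombination rate")

    @classmethod
    def uniform(cls, chrom_lengths: Mapping[str, int],
                rate_cM_per_Mb: float) -> "RecombinationMap":
        rows = [{"chrom": c, "start": 1, "end": L, "rate": rate_cM_per_Mb}
                for c, L in chrom_lengths.items()]
        return cls(pd.DataFrame(rows))

    def _segments(self, chrom: str):
        """Cached (starts, ends, cumulative Morgans) arrays per chromosome."""
        cache = self.__dict__.setdefault("_seg_cache", {})
        if chrom not in cache:
            sub = self.table[self.table["chrom"] == chrom].sort_values("start")
            if sub.empty:
                raise KeyError(f"no recombination map for chromosome {chrom!r}")
            starts = sub["start"].to_numpy(float)
            ends = sub["end"].to_numpy(float)
            seg_M = (ends - starts + 1) / 1e6 * sub["rate"].to_numpy() / 100.0
            cum = np.concatenate([[0.0], np.cumsum(seg_M)])
            cache[chrom] = (starts, ends, seg_M, cum)
        return cache[chrom]

    def genetic_length(self, chrom: str) -> float:
        """Total genetic length of a chromosome in Morgans."""
        return float(self._segments(chrom)[3][-1])

    def sample_crossovers(self, chrom: str, n: int,
                          rng: np.random.Generator) -> np.ndarray:
        """Physical positions of n crossovers, via the inverse cumulative
        genetic map (uniform on genetic distance)."""
        if n == 0:
            return np.empty(0)
        starts, ends, seg_M, cum = self._segments(chrom)
        u = rng.random(n) * cum[-1]
        seg = np.searchsorted(cum, u, side="right") - 1
        seg = np.clip(seg, 0, len(seg_M) - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = (u - cum[seg]) / seg_M[seg]
        frac = np.nan_to_num(frac, nan=0.5)
        return starts[seg] + frac * (ends[seg] - starts[seg] + 1)


@dataclass
class HaplotypePanel:
    """Phased haplotypes over a SNP list, with an optional recombination map.

    ``alleles`` is (H, S) int8 with 1 = rising allele, 0 = other allele and
    -1 = missing.  ``snps`` mirrors the tensor SNP table (chrom, pos, rising
    allele of the "1" state).
    """

    snps: pd.DataFrame  # columns chrom, pos, allele
    alleles: np.ndarray
    recombination_map: RecombinationMap | None = None
    haplotype_ids: list | None = None

    def __post_init__(self) -> None:
        if self.alleles.ndim != 2 or self.alleles.shape[1] != len(self.snps):
            raise ValueError("alleles shape inconsistent with SNP table")
        bad = ~np.isin(self.alleles, (-1, 0, 1))
        if bad.any():
            raise ValueError("haplotype alleles must be in {0, 1, missing}")
        if self.haplotype_ids is None:
            self.haplotype_ids = [f"h{i}" for i in range(self.alleles.shape[0])]
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"SNP positions not sorted on {chrom}")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-haplotype fraction of missing calls."""
        return (self.alleles == -1).mean(axis=1)

    def frequencies(self) -> np.ndarray:
        """Panel frequency of the "1" allele per SNP, over non-missing calls."""
        known = self.alleles >= 0
        with np.errstate(invalid="ignore"):
            return np.where(known, self.alleles, 0).sum(0) / known.sum(0)

    def column_keys(self) -> list[str]:
        return [f"{r.chrom}:{int(r.pos)}:{r.allele}"
                for r in self.snps.itertuples(index=False)]


def write_haplotypes(panel: HaplotypePanel, path: str | Path) -> None:
    """Haplotype matrix TSV: rows = haplotypes, columns keyed by
    ``chrom:pos:allele``, cells in {0, 1, .}.  A sidecar JSON run report
    (``<path>.report.json``) records dimensions and missingness."""
    path = Path(path)
    keys = panel.column_keys()
    with open(path, "w") as fh:
        fh.write("haplotype\t" + "\t".join(keys) + "\n")
        for hid, row in zip(panel.haplotype_ids, panel.alleles):
            cells = ["." if v < 0 else str(int(v)) for v in row]
            fh.write(str(hid) + "\t" + "\t".join(cells) + "\n")
    report = {
        "n_haplotypes": panel.n_haplotypes,
        "n_snps": panel.n_snps,
        "missing_fraction_max": float(panel.missing_fraction().max())
        if panel.n_haplotypes else 0.0,
    }
    with open(path.with_name(path.name + ".report.json"), "w") as fh:
        json.dump(report, fh, indent=2)


def read_haplotypes(path: str | Path,
                    recombination_map: RecombinationMap | None = None
                    ) -> HaplotypePanel:
    """Read a haplotype matrix TSV; duplicate column keys are an error."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        keys = header[1:]
        if len(set(keys)) != len(keys):
            dups = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate haplotype column keys: {dups}")
        ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(keys) + 1:
                raise ValueError(
                    f"haplotype row {parts[0]!r} has {len(parts)-1} cells, "
                    f"expected {len(keys)}")
            ids.append(parts[0])
            rows.append([-1 if c == "." else int(c) for c in parts[1:]])
    snps = pd.DataFrame(
        [(k.split(":")[0], int(k.split(":")[1]), k.split(":")[2])
         for k in keys], columns=["chrom", "pos", "allele"])
    return HaplotypePanel(snps=snps,
                          alleles=np.array(rows, dtype=np.int8),
                          recombination_map=recombination_map,
                          haplotype_ids=ids)


def align_panel(panel: HaplotypePanel, snps: pd.DataFrame) -> np.ndarray:
    """Column indices of ``panel`` matching the tensor SNP table rows
    (by chrom, pos, rising allele); -1 where absent.  A mismatch between
    position-matching columns and alleles raises an alignment error."""
    key_of = {(r.chrom, int(r.pos)): (i, r.allele)
              for i, r in enumerate(panel.snps.itertuples(index=False))}
    out = np.full(len(snps), -1, dtype=int)
    bad = []
    for j, row in enumerate(snps.itertuples(index=False)):
        hit = key_of.get((row.chrom, int(row.pos)))
        if hit is None:
            continue
        i, allele = hit
        if allele not in (row.rising, getattr(row, "other", row.rising)):
            bad.append(f"{row.chrom}:{row.pos}")
            continue
        out[j] = i
    if bad:
        raise ValueError("haplotype panel allele mismatch at columns: "
                         + ", ".join(bad[:10]))
    return out


# ---------------------------------------------------------------------------
# chromosome-arm concatenation


def merge_arms(tensor: AlleleCountTensor,
               pairs: Mapping[str, tuple[str, str]],
               arm_lengths: Mapping[str, int]) -> AlleleCountTensor:
    """Concatenate left/right chromosome arms (e.g. 2L+2R -> "2").

    Right-arm positions are offset by the stated left-arm length; the offsets
    used are recorded in ``tensor.meta['arm_offsets']``.  Blocks spanning a
    centromere then fall inside one coordinate system for windowing.
    """
    snps = tensor.snps.copy()
    offsets = {}
    for merged, (left, right) in pairs.items():
        off = int(arm_lengths[left])
        offsets[right] = off
        snps.loc[snps["chrom"] == right, "pos"] += off
        snps.loc[snps["chrom"].isin([left, right]), "chrom"] = merged
    out = AlleleCountTensor(snps=snps, replicates=list(tensor.replicates),
                            generations=tensor.generations.copy(),
                            rising_count=tensor.rising_count.copy(),
                            coverage=tensor.coverage.copy(),
                            meta=dict(tensor.meta))
    out.meta["arm_offsets"] = offsets
    return out.sorted_by_position()
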