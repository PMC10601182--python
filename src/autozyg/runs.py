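"""Consecutive-runs detection of ROH and heterozygosity-rich regions.

A run of homozygosity (ROH) is a stretch of consecutive SNPs that is
essentially homozygous; a heterozygosity-rich region (HRR) is the mirror
image, a short stretch dense in heterozygous calls.  Both are detected
with the consecutive-runs approach: a candidate window grows SNP by SNP
along a chromosome while

  * opposite-state SNPs in the window   <= max_opposite,
  * missing SNPs in the window          <= max_missing,
  * every gap between consecutive SNPs  <= max_gap_bp,

a window must start and end on a SNP of the run's own state, and emitted
runs must reach min_snps and min_length_bp.  ``detect_runs`` enumerates
every *maximal* conforming window (two windows may overlap when an
interruption budget forces a trade-off between extending left or right);
the test suite checks it against a brute-force enumeration oracle.

Coordinates are 1-based inclusive; run length = end_bp - start_bp + 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1  # genotype sentinel in the 0/1/2 allele-count coding

ROH = "ROH"
HRR = "HRR"


class GenotypeError(ValueError):
    """Invalid genotype data (unknown codes, misaligned map)."""


@dataclass(frozen=True)
class RunParams:
    """Consecutive-runs parameters.

    Defaults match common array-density choices: ROH 20/5/5/1 kb/1 Mb
    (min SNPs / max heterozygous / max missing / min length / max gap),
    HRR 10/5/5/1 kb/1 Mb.
    """

    min_snps: int
    max_opposite: int
    max_missing: int
    min_length_bp: int = 1_000
    max_gap_bp: int = 1_000_000

    def __post_init__(self):
        if min(self.min_snps, self.min_length_bp, self.max_gap_bp) <= 0 \
                or self.max_opposite < 0 or self.max_missing < 0:
            raise ValueError("run parameters must be positive")
        if self.max_opposite >= self.min_snps:
            raise ValueError("max_opposite must be < min_snps")


ROH_DEFAULTS = RunParams(min_snps=20, max_opposite=5, max_missing=5)
HRR_DEFAULTS = RunParams(min_snps=10, max_opposite=5, max_missing=5)


@dataclass(frozen=True)
class RunSegment:
    individual: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    kind: str

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


class MarkerMap:
    """SNP map: name, chromosome, bp position, sorted within chromosome."""

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        need = {"name", "chrom", "pos_bp"}
        if need - set(df.columns):
            raise GenotypeError(f"marker map needs columns {sorted(need)}")
        df["chrom"] = df["chrom"].astype(str)
        df["pos_bp"] = df["pos_bp"].astype(np.int64)
        if (df["pos_bp"] <= 0).any():
            raise GenotypeError("bp positions must be positive")
        for chrom, grp in df.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["pos_bp"].to_numpy()) > 0):
                raise GenotypeError(f"positions not strictly increasing on chromosome {chrom}")
        self.df = df.reset_index(drop=True)
        self._chrom_slices = {}
        chroms = self.df["chrom"].to_numpy()
        start = 0
        for k in range(1, len(chroms) + 1):
            if k == len(chroms) or chroms[k] != chroms[start]:
                self._chrom_slices[chroms[start]] = slice(start, k)
                start = k

    def __len__(self):
        return len(self.df)

    @property
    def chroms(self) -> list:
        return list(self._chrom_slices)

    def chrom_slice(self, chrom) -> slice:
        return self._chrom_slices[str(chrom)]

    def chrom_span(self, chrom) -> int:
        """last SNP bp - first SNP bp + 1 on the chromosome."""
        sl = self.chrom_slice(chrom)
        pos = self.df["pos_bp"].to_numpy()
        return int(pos[sl.stop - 1] - pos[sl.start] + 1)

    def autosome_length(self, scope="genome", override=None) -> int:
        """L_AUTO: the scope's map span (sum of per-chromosome spans)."""
        if override is not None:
            if scope == "genome":
                return int(sum(override.values()))
            return int(override[str(scope)])
        if scope == "genome":
            return sum(self.chrom_span(c) for c in self.chroms)
        return self.chrom_span(scope)


class GenotypeMatrix:
    """Individuals x SNPs allele counts (0/1/2, MISSING = -1), int8."""

    def __init__(self, ids, matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=np.int8)
        if matrix.ndim != 2 or matrix.shape[0] != len(ids):
            raise GenotypeError("genotype matrix shape does not match ids")
        bad = ~np.isin(matrix, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeError("genotype codes must be 0/1/2 or missing")
        self.ids = [str(i) for i in ids]
        self.matrix = matrix
        self._row = {iid: k for k, iid in enumerate(self.ids)}

    @property
    def n_individuals(self):
        return len(self.ids)

    @property
    def n_snps(self):
        return self.matrix.shape[1]

    def vector(self, iid: str) -> np.ndarray:
        return self.matrix[self._row[str(iid)]]

    def subset_snps(self, keep_mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.ids, self.matrix[:, keep_mask])

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        rows = [self._row[str(i)] for i in ids]
        return GenotypeMatrix([self.ids[r] for r in rows], self.matrix[rows])


# ---------------------------------------------------------------------------
# run detection
# ---------------------------------------------------------------------------

def _states(vec: np.ndarray, kind: str):
    """(conforming, opposite, missing) boolean masks for the run kind."""
    missing = vec == MISSING
    het = vec == 1
    if kind == ROH:
        conform = (~missing) & (~het)
        opposite = het
    elif kind == HRR:
        conform = het
        opposite = (~missing) & (~het)
    else:
        raise ValueError(f"unknown run kind {kind!r}")
    return conform, opposite, missing


def detect_runs(genotypes: np.ndarray, marker_map: MarkerMap, params: RunParams,
                kind: str, individual: str = "") -> list:
    """Detect all maximal conforming runs of one kind for one individual.

    Within each chromosome, stretches are first split at gaps larger than
    max_gap_bp (a large gap closes any run).  Within a stretch, for every
    conforming start the maximal feasible conforming end is found with a
    two-pointer sweep (interruption counts via prefix sums); a window is
    emitted when no conforming window strictly contains it.
    """
    genotypes = np.asarray(genotypes)
    if genotypes.shape[0] != len(marker_map):
        raise GenotypeError("genotype vector not aligned to marker map")
    if not np.isin(genotypes, (0, 1, 2, MISSING)).all():
        raise GenotypeError("unknown genotype code in vector")

    out = []
    pos_all = marker_map.df["pos_bp"].to_numpy()
    for chrom in marker_map.chroms:
        sl = marker_map.chrom_slice(chrom)
        pos = pos_all[sl]
        vec = genotypes[sl]
        conform, opposite, missing = _states(vec, kind)
        # split at oversized gaps
        breaks = np.flatnonzero(np.diff(pos) > params.max_gap_bp)
        starts = np.concatenate(([0], breaks + 1))
        stops = np.concatenate((breaks + 1, [len(pos)]))
        copp = np.concatenate(([0], np.cumsum(opposite)))
        cmis = np.concatenate(([0], np.cumsum(missing)))
        for lo, hi in zip(starts, stops):  # block [lo, hi)
            conf_idx = np.flatnonzero(conform[lo:hi]) + lo
            if conf_idx.size == 0:
                continue
            # last conforming index at or before each position in the block
            last_conf = np.maximum.accumulate(
                np.where(conform[lo:hi], np.arange(lo, hi), -1))
            r = -1
            prev_end = -2
            for i in conf_idx:
                if r < i:
                    r = i
                while r + 1 < hi \
                        and copp[r + 2] - copp[i] <= params.max_opposite \
                        and cmis[r + 2] - cmis[i] <= params.max_missing:
                    r += 1
                e = last_conf[r - lo]
                if e == prev_end:
                    continue  # contained in the previous maximal window
                prev_end = e
                n_snps = int(e - i + 1)
                length = int(pos[e] - pos[i] + 1)
                if n_snps >= params.min_snps and length >= params.min_length_bp:
                    out.append(RunSegment(individual=str(individual), chrom=str(chrom),
                                          start_bp=int(pos[i]), end_bp=int(pos[e]),
                                          n_snps=n_snps, kind=kind))
    return out


def detect_all_runs(geno: GenotypeMatrix, marker_map: MarkerMap, params: RunParams,
                    kind: str) -> list:
    """detect_runs for every individual in the matrix."""
    segments = []
    for iid in geno.ids:
        segments.extend(detect_runs(geno.vector(iid), marker_map, params, kind, iid))
    return segments


def merge_regions(segments) -> pd.DataFrame:
    """Union-merge run segments across individuals into population regions.

    Returns a DataFrame (chrom, start_bp, end_bp, n_individuals) where
    n_individuals counts distinct contributors per merged region.
    Segments must all be of one kind.
    """
    segments = list(segments)
    if not segments:
        return pd.DataFrame(columns=["chrom", "start_bp", "end_bp", "n_individuals"])
    kinds = {s.kind for s in segments}
    if len(kinds) > 1:
        raise ValueError(f"segments of mixed kinds: {sorted(kinds)}")
    rows = []
    by_chrom = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in sorted(by_chrom, key=lambda c: (len(c), c)):
        segs = sorted(by_chrom[chrom], key=lambda s: (s.start_bp, s.end_bp))
        cur_start, cur_end = segs[0].start_bp, segs[0].end_bp
        members = {segs[0].individual}
        for s in segs[1:]:
            if s.start_bp <= cur_end:  # 1-based inclusive overlap
                cur_end = max(cur_end, s.end_bp)
                members.add(s.individual)
            else:
                rows.append((chrom, cur_start, cur_end, len(members)))
                cur_start, cur_end, members = s.start_bp, s.end_bp, {s.individual}
        rows.append((chrom, cur_start, cur_end, len(members)))
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "n_individuals"])


# ---------------------------------------------------------------------------
# Mendelian-error SNP filter
# ---------------------------------------------------------------------------

def _mendel_possible() -> np.ndarray:
    """possible[a, b, c]: can parents with counts a,b produce offspring c."""
    gametes = {0: (0,), 1: (0, 1), 2: (1,)}
    table = np.zeros((3, 3, 3), dtype=bool)
    for a in range(3):
        for b in range(3):
            for ga in gametes[a]:
                for gb in gametes[b]:
                    table[a, b, ga + gb] = True
    return table


_POSSIBLE = _mendel_possible()


@dataclass
class MendelReport:
    removed_snps: list
    n_trios: int
    errors_per_snp: pd.Series      # index snp name, only removed SNPs
    errors_per_trio: pd.DataFrame  # offspring, sire, dam, n_errors


def mendelian_filter(geno: GenotypeMatrix, ped, marker_map: MarkerMap):
    """Drop SNPs showing >= 1 parents-offspring trio inconsistency.

    Trios are formed from genotyped offspring whose sire and dam are both
    genotyped.  Cells with a missing genotype in any trio member do not
    contribute evidence at that SNP.
    """
    trios = []
    for iid in geno.ids:
        if iid not in ped:
            continue
        sire, dam = ped.parents_of(iid)
        if sire in geno._row and dam in geno._row:
            trios.append((iid, sire, dam))
    if not trios:
        warnings.warn("no resolvable trios; Mendelian filter is a pass-through")
        empty = pd.DataFrame(columns=["offspring", "sire", "dam", "n_errors"])
        return geno, marker_map, MendelReport([], 0, pd.Series(dtype=int), empty)

    n_snps = geno.n_snps
    err_snp = np.zeros(n_snps, dtype=np.int64)
    trio_rows = []
    for off, sire, dam in trios:
        o, s, d = geno.vector(off), geno.vector(sire), geno.vector(dam)
        ok_mask = (o != MISSING) & (s != MISSING) & (d != MISSING)
        errs = np.zeros(n_snps, dtype=bool)
        errs[ok_mask] = ~_POSSIBLE[s[ok_mask], d[ok_mask], o[ok_mask]]
        err_snp += errs
        trio_rows.append((off, sire, dam, int(errs.sum())))

    bad = err_snp > 0
    names = marker_map.df["name"].to_numpy()
    report = MendelReport(
        removed_snps=list(names[bad]),
        n_trios=len(trios),
        errors_per_snp=pd.Series(err_snp[bad], index=names[bad], name="n_errors"),
        errors_per_trio=pd.DataFrame(trio_rows, columns=["offspring", "sire", "dam", "n_errors"]),
    )
    filtered = geno.subset_snps(~bad)
    filtered_map = MarkerMap(marker_map.df.loc[~bad].reset_index(drop=True))
    return filtered, filtered_map, report
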