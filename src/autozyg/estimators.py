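"""Four per-individual genomic homozygosity estimators.

F_ROH : fraction of the autosomal map span covered by runs of
        homozygosity, sum(L_ROH) / L_AUTO.
F_HRR : 1 - sum(L_HRR) / L_AUTO, the complement of the fraction covered
        by heterozygosity-rich regions.
F_LH  : Li & Horvitz excess homozygosity relative to Hardy-Weinberg
        expectation at base-population (BP) allele frequencies,
        (S*F_NEJ - E) / (S - E) with E = sum_k [1 - 2 p_k (1 - p_k)]
        and F_NEJ the observed fraction of homozygous loci.
F_YAN : Yang et al. correlation between uniting gametes, the mean over
        SNPs of (x^2 - (1 + 2p) x + 2p^2) / (2p(1-p)).

L_AUTO is taken as the marker-map span (per chromosome: last - first
SNP bp + 1), overridable with assembly lengths.  SNPs monomorphic in
the BP are excluded from F_LH / F_YAN (their denominators are singular)
but still participate in run detection.  Missing genotypes are dropped
SNP-wise from S.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .runs import MISSING, ROH, HRR, GenotypeMatrix, MarkerMap

GENOME = "genome"


@dataclass
class BasePopulation:
    """Reference-allele frequencies and membership of the base population."""

    member_ids: tuple
    p0: np.ndarray                 # per-SNP reference-allele frequency in the BP
    monomorphic_in_bp: np.ndarray  # p0 in {0,1} or not callable in the BP

    @classmethod
    def from_genotypes(cls, geno: GenotypeMatrix, member_ids) -> "BasePopulation":
        member_ids = tuple(str(i) for i in member_ids)
        sub = geno.subset_individuals(member_ids).matrix
        called = sub != MISSING
        counts = np.where(called, sub, 0).sum(axis=0)
        n_alleles = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p0 = np.where(n_alleles > 0, counts / np.maximum(n_alleles, 1), np.nan)
        mono = ~np.isfinite(p0) | (p0 <= 0.0) | (p0 >= 1.0)
        return cls(member_ids=member_ids, p0=p0, monomorphic_in_bp=mono)


def _scope_mask(marker_map: MarkerMap, scope) -> np.ndarray:
    if scope == GENOME:
        return np.ones(len(marker_map), dtype=bool)
    mask = np.zeros(len(marker_map), dtype=bool)
    mask[marker_map.chrom_slice(scope)] = True
    return mask


def _sum_lengths(segments, kind, scope) -> int:
    """Covered length: the union of the segment intervals per chromosome
    (maximal conforming windows may overlap; coverage counts once)."""
    by_chrom = {}
    for s in segments:
        if s.kind != kind:
            raise ValueError(f"expected {kind} segments, got {s.kind}")
        if scope == GENOME or s.chrom == str(scope):
            by_chrom.setdefault(s.chrom, []).append((s.start_bp, s.end_bp))
    total = 0
    for intervals in by_chrom.values():
        intervals.sort()
        cur_start, cur_end = intervals[0]
        for start, end in intervals[1:]:
            if start <= cur_end:
                cur_end = max(cur_end, end)
            else:
                total += cur_end - cur_start + 1
                cur_start, cur_end = start, end
        total += cur_end - cur_start + 1
    return total


def f_roh(segments, marker_map: MarkerMap, scope=GENOME, *, l_auto_override=None) -> float:
    """sum(L_ROH) / L_AUTO within the scope ('genome' or a chromosome)."""
    l_auto = marker_map.autosome_length(scope, override=l_auto_override)
    if l_auto <= 0:
        return float("nan")
    return _sum_lengths(segments, ROH, scope) / l_auto


def f_hrr(segments, marker_map: MarkerMap, scope=GENOME, *, l_auto_override=None) -> float:
    """1 - sum(L_HRR) / L_AUTO within the scope."""
    l_auto = marker_map.autosome_length(scope, override=l_auto_override)
    if l_auto <= 0:
        return float("nan")
    return 1.0 - _sum_lengths(segments, HRR, scope) / l_auto


def f_lh(geno_vector: np.ndarray, bp: BasePopulation, marker_map: MarkerMap,
         scope=GENOME) -> float:
    """Li & Horvitz homozygosity excess over the BP expectation."""
    use = _scope_mask(marker_map, scope) & ~bp.monomorphic_in_bp \
        & (np.asarray(geno_vector) != MISSING)
    S = int(use.sum())
    if S == 0:
        return float("nan")
    x = np.asarray(geno_vector)[use]
    p = bp.p0[use]
    exp_hom = np.sum(1.0 - 2.0 * p * (1.0 - p))
    if S - exp_hom <= 0:
        return float("nan")
    f_nej = np.mean(x != 1)
    return float((S * f_nej - exp_hom) / (S - exp_hom))


def f_yan(geno_vector: np.ndarray, bp: BasePopulation, marker_map: MarkerMap,
          scope=GENOME) -> float:
    """Yang et al. diagonal of the genomic relationship matrix."""
    use = _scope_mask(marker_map, scope) & ~bp.monomorphic_in_bp \
        & (np.asarray(geno_vector) != MISSING)
    if not use.any():
        return float("nan")
    x = np.asarray(geno_vector)[use].astype(float)
    p = bp.p0[use]
    terms = (x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / (2.0 * p * (1.0 - p))
    return float(terms.mean())


def homozygosity_table(geno: GenotypeMatrix, marker_map: MarkerMap,
                       roh_segments, hrr_segments, bp: BasePopulation,
                       *, l_auto_override=None) -> pd.DataFrame:
    """Raw values of the four estimators, genome-wide and per autosome.

    Returns a DataFrame indexed by individual with MultiIndex columns
    (estimator in {F_ROH, F_HRR, F_LH, F_YAN}, scope in {'genome'} + chroms).
    """
    scopes = [GENOME] + [str(c) for c in marker_map.chroms]
    by_ind = {"ROH": {}, "HRR": {}}
    for seg in roh_segments:
        by_ind["ROH"].setdefault(seg.individual, []).append(seg)
    for seg in hrr_segments:
        by_ind["HRR"].setdefault(seg.individual, []).append(seg)

    cols = pd.MultiIndex.from_product(
        [["F_ROH", "F_HRR", "F_LH", "F_YAN"], scopes], names=["estimator", "scope"])
    data = {c: np.empty(len(geno.ids)) for c in cols}
    for k, iid in enumerate(geno.ids):
        vec = geno.vector(iid)
        segs_roh = by_ind["ROH"].get(iid, [])
        segs_hrr = by_ind["HRR"].get(iid, [])
        for scope in scopes:
            data[("F_ROH", scope)][k] = f_roh(
                segs_roh, marker_map, scope, l_auto_override=l_auto_override)
            data[("F_HRR", scope)][k] = f_hrr(
                segs_hrr, marker_map, scope, l_auto_override=l_auto_override)
            data[("F_LH", scope)][k] = f_lh(vec, bp, marker_map, scope)
            data[("F_YAN", scope)][k] = f_yan(vec, bp, marker_map, scope)
    out = pd.DataFrame(data, index=pd.Index(geno.ids, name="id"))
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["estimator", "scope"])
    return out


def regress_on_t(values, t) -> tuple:
    """OLS of an estimator on pedigree depth t: (slope, p_value, R^2)."""
    values = np.asarray(values, dtype=float)
    t = np.asarray(t, dtype=float)
    ok = np.isfinite(values) & np.isfinite(t)
    if ok.sum() < 3:
        raise ValueError("need at least 3 defined (value, t) points")
    if np.ptp(t[ok]) == 0:
        return float("nan"), float("nan"), float("nan")
    res = stats.linregress(t[ok], values[ok])
    return float(res.slope), float(res.pvalue), float(res.rvalue ** 2)
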