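"""Consecutive-runs detection, region merging, Mendelian filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import autozyg as az
from autozyg.runs import GenotypeError, MISSING

from conftest import make_pedigree_table
from oracles import enumerate_max_windows


def single_chrom_map(positions, chrom="1"):
    return az.MarkerMap(pd.DataFrame({
        "name": [f"snp{k}" for k in range(len(positions))],
        "chrom": chrom, "pos_bp": positions}))


ROH_P = az.ROH_DEFAULTS
HRR_P = az.HRR_DEFAULTS


class TestDetectRuns:
    def test_clean_homozygous_stretch(self):
        pos = np.arange(1, 26) * 83_000  # 25 SNPs spanning about 2 Mb
        mm = single_chrom_map(pos)
        vec = np.full(25, 2, dtype=np.int8)
        (run,) = az.detect_runs(vec, mm, ROH_P, az.ROH, "ind")
        assert (run.n_snps, run.start_bp, run.end_bp) == (25, 83_000, 25 * 83_000)

    def test_large_gap_splits_below_min_snps(self):
        pos = np.concatenate([np.arange(1, 13) * 10_000,
                              1_700_000 + np.arange(13) * 10_000])
        mm = single_chrom_map(pos)
        vec = np.zeros(25, dtype=np.int8)
        assert az.detect_runs(vec, mm, ROH_P, az.ROH) == []

    def test_heterozygote_budget_matches_oracle(self, rng):
        # 60 SNPs, 6 interspersed heterozygotes under a 5-het budget
        pos = np.arange(1, 61) * 50_000
        mm = single_chrom_map(pos)
        vec = np.zeros(60, dtype=np.int8)
        het_at = rng.choice(60, size=6, replace=False)
        vec[het_at] = 1
        runs = az.detect_runs(vec, mm, ROH_P, az.ROH)
        expected = enumerate_max_windows(vec, pos, ROH_P, az.ROH)
        assert [(r.start_bp, r.end_bp) for r in runs] == \
            [(int(pos[i]), int(pos[j])) for i, j in expected]

    def test_unknown_code_fatal(self):
        mm = single_chrom_map([100, 200])
        with pytest.raises(GenotypeError):
            az.detect_runs(np.array([0, 7]), mm, ROH_P, az.ROH)

    def test_runs_never_span_chromosomes(self):
        mm = az.MarkerMap(pd.DataFrame({
            "name": [f"s{k}" for k in range(50)],
            "chrom": ["1"] * 25 + ["2"] * 25,
            "pos_bp": list(np.arange(1, 26) * 50_000) * 2}))
        vec = np.zeros(50, dtype=np.int8)
        runs = az.detect_runs(vec, mm, ROH_P, az.ROH)
        assert {r.chrom for r in runs} == {"1", "2"}

    @given(data=st.data())
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_oracle_equivalence_random_vectors(self, data):
        n = data.draw(st.integers(5, 120))
        codes = data.draw(st.lists(
            st.sampled_from([0, 1, 2, MISSING]), min_size=n, max_size=n))
        gaps = data.draw(st.lists(
            st.integers(1, 1_400_000), min_size=n, max_size=n))
        pos = np.cumsum(gaps)
        vec = np.array(codes, dtype=np.int8)
        mm = single_chrom_map(pos)
        params = az.RunParams(min_snps=data.draw(st.integers(2, 12)),
                              max_opposite=1, max_missing=1,
                              min_length_bp=1000, max_gap_bp=1_000_000)
        for kind in (az.ROH, az.HRR):
            got = [(r.start_bp, r.end_bp, r.n_snps)
                   for r in az.detect_runs(vec, mm, params, kind)]
            want = [(int(pos[i]), int(pos[j]), j - i + 1)
                    for i, j in enumerate_max_windows(vec, pos, params, kind)]
            assert got == want

    @given(data=st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_allele_relabel_invariance(self, data):
        n = data.draw(st.integers(10, 80))
        codes = data.draw(st.lists(
            st.sampled_from([0, 1, 2, MISSING]), min_size=n, max_size=n))
        vec = np.array(codes, dtype=np.int8)
        swapped = np.where(vec == MISSING, MISSING, 2 - vec).astype(np.int8)
        pos = np.cumsum(np.full(n, 40_000))
        mm = single_chrom_map(pos)
        p = az.RunParams(min_snps=4, max_opposite=1, max_missing=1)
        for kind in (az.ROH, az.HRR):
            assert az.detect_runs(vec, mm, p, kind) == \
                az.detect_runs(swapped, mm, p, kind)

    def test_run_boundaries_are_conforming_and_coverage_bounded(self, rng):
        pos = np.sort(rng.choice(5_000_000, size=300, replace=False)) + 1
        mm = single_chrom_map(pos)
        vec = rng.choice([0, 1, 2, 2, 0], size=300).astype(np.int8)
        for kind, params in ((az.ROH, ROH_P), (az.HRR, HRR_P)):
            runs = az.detect_runs(vec, mm, params, kind)
            covered = 0
            last_end = 0
            for r in runs:
                for bp in (r.start_bp, r.end_bp):
                    g = vec[np.flatnonzero(pos == bp)[0]]
                    assert g != MISSING
                    assert (g == 1) == (kind == az.HRR)
                covered += max(0, r.end_bp - max(last_end + 1, r.start_bp) + 1)
                last_end = max(last_end, r.end_bp)
            assert covered <= mm.chrom_span("1")


class TestMergeRegions:
    def test_identical_segments_counted_once_per_individual(self):
        segs = [az.RunSegment(i, "1", 100, 200, 10, az.ROH) for i in ("a", "b")]
        regions = az.merge_regions(segs)
        assert len(regions) == 1
        assert regions.loc[0, "n_individuals"] == 2

    def test_disjoint_segments_stay_separate(self):
        segs = [az.RunSegment("a", "1", 100, 200, 10, az.ROH),
                az.RunSegment("a", "1", 300, 400, 10, az.ROH)]
        assert len(az.merge_regions(segs)) == 2

    def test_staircase_collapses_to_single_span(self):
        segs = [az.RunSegment(i, "1", s, e, 5, az.HRR)
                for i, (s, e) in zip("abc", [(100, 250), (200, 350), (300, 450)])]
        regions = az.merge_regions(segs)
        assert regions.iloc[0].tolist() == ["1", 100, 450, 3]

    def test_mixed_kinds_rejected(self):
        segs = [az.RunSegment("a", "1", 1, 2, 1, az.ROH),
                az.RunSegment("a", "1", 1, 2, 1, az.HRR)]
        with pytest.raises(ValueError, match="mixed"):
            az.merge_regions(segs)


class TestMendelianFilter:
    def _setup(self, offspring_genotypes):
        ped = make_pedigree_table({"S": (None, None), "D": (None, None),
                                   "O": ("S", "D")})
        n = len(offspring_genotypes)
        mm = single_chrom_map(np.arange(1, n + 1) * 1000)
        sire = np.zeros(n, dtype=np.int8)          # S: 0 everywhere
        dam = np.array([0, 2, 2, 1][:n], np.int8)  # per-case parent genotypes
        geno = az.GenotypeMatrix(
            ["S", "D", "O"], np.vstack([sire, dam, offspring_genotypes]))
        return ped, geno, mm

    def test_trio_inconsistencies_remove_snps(self):
        # SNP1: parents {0,0}, offspring 2 -> impossible; SNP2: {0,2} offspring 1 ok
        # SNP3: {0,2} offspring 0 -> impossible; SNP4: {0,1} offspring 1 ok
        ped, geno, mm = self._setup(np.array([2, 1, 0, 1], dtype=np.int8))
        fgeno, fmap, report = az.mendelian_filter(geno, ped, mm)
        assert report.removed_snps == ["snp0", "snp2"]
        assert fgeno.n_snps == 2
        assert report.errors_per_trio.loc[0, "n_errors"] == 2

    def test_missing_genotype_is_no_evidence(self):
        ped, geno, mm = self._setup(np.array([MISSING, 1, MISSING, 1], dtype=np.int8))
        fgeno, fmap, report = az.mendelian_filter(geno, ped, mm)
        assert report.removed_snps == []
        assert fgeno.n_snps == 4

    def test_no_trios_warns_and_passes_through(self):
        ped = make_pedigree_table({"X": (None, None)})
        mm = single_chrom_map([1000])
        geno = az.GenotypeMatrix(["X"], np.array([[0]], dtype=np.int8))
        with pytest.warns(UserWarning, match="no resolvable trios"):
            fgeno, fmap, report = az.mendelian_filter(geno, ped, mm)
        assert fgeno.n_snps == 1
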