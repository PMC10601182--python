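"""Genealogical statistics: F, kinship, t/G, dF, dC, cohorts, Ne."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import autozyg as az
from autozyg.pedigree import PedigreeError

from conftest import make_pedigree_table
from oracles import gene_drop_kinship, inbreeding_recursive, kinship_recursive, \
    random_pedigree


class TestLoadAndValidate:
    def test_minimal_pedigree(self, tmp_path):
        p = tmp_path / "ped.csv"
        p.write_text("id,sire,dam\nA,0,0\nB,,\nC,A,B\n")
        ped = az.load_pedigree(p)
        assert len(ped) == 3
        assert sorted(ped.founders()) == ["A", "B"]
        assert ped.parents_of("C") == ("A", "B")

    def test_duplicate_id_fatal(self):
        df = pd.DataFrame({"id": ["A", "A"], "sire": ["0", "0"], "dam": ["0", "0"]})
        with pytest.raises(PedigreeError, match="duplicate"):
            az.PedigreeTable(df)

    def test_cycle_fatal_with_chain(self):
        # A is its own grandparent via B
        df = pd.DataFrame({"id": ["A", "B"], "sire": ["B", "A"], "dam": ["0", "0"]})
        with pytest.raises(PedigreeError, match="cycle.*A.*B|cycle.*B.*A"):
            az.PedigreeTable(df)

    def test_birth_year_before_parent_fatal(self):
        df = pd.DataFrame({"id": ["A", "B"], "sire": ["0", "A"], "dam": ["0", "0"],
                           "birth_year": [2005, 2000]})
        with pytest.raises(PedigreeError, match="born"):
            az.PedigreeTable(df)

    def test_parent_only_ids_become_founders(self):
        df = pd.DataFrame({"id": ["C"], "sire": ["A"], "dam": ["B"]})
        ped = az.PedigreeTable(df)
        assert sorted(ped.founders()) == ["A", "B"]


class TestInbreeding:
    def test_classical_closed_forms(self, fullsib_pedigree, halfsib_pedigree):
        F = az.inbreeding_meuwissen_luo(fullsib_pedigree)
        assert F["C"] == 0.0  # offspring of unrelated founders
        assert F["E"] == pytest.approx(0.25, abs=1e-12)  # full-sib mating
        F2 = az.inbreeding_meuwissen_luo(halfsib_pedigree)
        assert F2["O"] == pytest.approx(0.125, abs=1e-12)  # half-sib mating

    def test_matches_recursive_oracle_on_random_pedigrees(self, rng):
        for _ in range(25):
            parents = random_pedigree(rng, n_max=40)
            ped = make_pedigree_table(parents)
            F = az.inbreeding_meuwissen_luo(ped)
            expected = inbreeding_recursive(parents)
            for iid in parents:
                assert F[iid] == pytest.approx(expected[iid], abs=1e-12)

    def test_tabular_diagonal_consistent_with_meuwissen_luo(self, rng):
        parents = random_pedigree(rng, n_max=30)
        ped = make_pedigree_table(parents)
        F = az.inbreeding_meuwissen_luo(ped)
        K = az.kinship_matrix(ped)
        for iid in parents:
            assert K.loc[iid, iid] == pytest.approx(0.5 * (1 + F[iid]), abs=1e-12)


class TestCoancestry:
    def test_closed_forms(self, fullsib_pedigree):
        pairs = az.coancestry(fullsib_pedigree, [("A", "B"), ("C", "D"), ("A", "C")])
        by = {(p.i, p.j): p.C for p in pairs}
        assert by[("A", "B")] == 0.0
        assert by[("C", "D")] == 0.25   # full sibs
        assert by[("A", "C")] == 0.25   # parent-offspring

    def test_gene_dropping_monte_carlo_agreement(self, fullsib_pedigree, rng):
        parents = {"A": (None, None), "B": (None, None),
                   "C": ("A", "B"), "D": ("A", "B"), "E": ("C", "D")}
        mc = gene_drop_kinship(parents, ("C", "D"), 4000, rng)
        assert mc == pytest.approx(0.25, abs=3 * math.sqrt(0.25 * 0.75 / 4000))

    def test_self_coancestry_identity(self, rng):
        parents = random_pedigree(rng, n_max=30)
        ped = make_pedigree_table(parents)
        K = az.kinship_matrix(ped)
        F = az.inbreeding_meuwissen_luo(ped)
        for iid in parents:
            assert K.loc[iid, iid] == pytest.approx((1 + F[iid]) / 2, abs=1e-12)


class TestPedigreeDepth:
    @pytest.mark.parametrize("target,expected", [
        ("A", (0, 0.0)),      # founder
        ("C", (1, 1.0)),      # both parents founders
        ("E", (2, 2.0)),      # all four grandparents founders
    ])
    def test_depth_examples(self, fullsib_pedigree, target, expected):
        gt = az.equivalent_generations(fullsib_pedigree)
        assert gt[target] == expected

    def test_one_founder_parent(self):
        # sire founder; dam has two founder parents: t = 0.5 + 0.5 + 2*0.25
        ped = make_pedigree_table({"S": (None, None), "G1": (None, None),
                                   "G2": (None, None), "D": ("G1", "G2"),
                                   "X": ("S", "D")})
        gt = az.equivalent_generations(ped)
        assert gt["X"] == (1, 1.5)

    def test_t_monotone_when_ancestors_added(self):
        without = make_pedigree_table({"D": (None, None), "X": (None, "D")})
        with_anc = make_pedigree_table({"G1": (None, None), "G2": (None, None),
                                        "D": ("G1", "G2"), "X": (None, "D")})
        t0 = az.equivalent_generations(without)["X"][1]
        t1 = az.equivalent_generations(with_anc)["X"][1]
        assert t1 > t0


class TestIncreaseFormulas:
    @pytest.mark.parametrize("F,t,expected", [
        (0.0, 5.0, 0.0),
        (0.25, 2.0, 0.25),
        (0.19, 3.0, 0.1),  # 1 - sqrt(0.81)
    ])
    def test_delta_F_examples(self, F, t, expected):
        assert az.delta_F_individual(F, t) == pytest.approx(expected, abs=1e-12)

    def test_delta_F_undefined_for_shallow_pedigrees(self):
        assert math.isnan(az.delta_F_individual(0.2, 1.0))
        assert math.isnan(az.delta_F_individual(0.2, 0.5))

    @given(F=st.floats(0.01, 0.9), t=st.floats(1.1, 6.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_delta_F_monotonicity(self, F, t):
        base = az.delta_F_individual(F, t)
        assert az.delta_F_individual(min(F + 0.05, 0.95), t) > base
        assert az.delta_F_individual(F, t + 0.5) < base

    @pytest.mark.parametrize("C,ti,tj,expected", [
        (0.0, 3.0, 1.0, 0.0),
        (0.25, 1.0, 1.0, 0.25),
        (0.19, 2.0, 2.0, 0.1),
    ])
    def test_delta_C_examples(self, C, ti, tj, expected):
        assert az.delta_C_pairwise(C, ti, tj) == pytest.approx(expected, abs=1e-12)


class TestCohortsAndNe:
    def _pedigree_with_years(self):
        rows = {"id": [], "sire": [], "dam": [], "birth_year": []}
        rows["id"] += ["A", "B"]; rows["sire"] += ["0", "0"]
        rows["dam"] += ["0", "0"]; rows["birth_year"] += [2000, 2000]
        for k in range(4):
            rows["id"].append(f"S{k}"); rows["sire"].append("A")
            rows["dam"].append("B"); rows["birth_year"].append(2001)
        for k in range(3):
            rows["id"].append(f"O{k}"); rows["sire"].append("S0")
            rows["dam"].append("S1"); rows["birth_year"].append(2002 + (k == 2))
        return az.PedigreeTable(pd.DataFrame(rows))

    def test_year_scheme_with_merge(self):
        ped = self._pedigree_with_years()
        cohorts = {c.label: c for c in az.define_cohorts(
            ped, "year", merge_years={2003: 2002})}
        assert cohorts["C2002"].n == 3  # 2003-born absorbed
        assert cohorts["C2001"].mean_t == 1.0

    def test_t_threshold_subset(self):
        ped = self._pedigree_with_years()
        (cohort,) = az.define_cohorts(ped, "t_threshold", t_threshold=2.0)
        assert set(cohort.member_ids) == {"O0", "O1", "O2"}

    def test_founder_only_pedigree_gives_empty_t_subset(self):
        ped = make_pedigree_table({"A": (None, None), "B": (None, None)})
        with pytest.warns(UserWarning):
            assert az.define_cohorts(ped, "t_threshold") == []

    def test_ne_from_known_mean(self):
        # full-sib offspring: F = 0.25, t = 2 -> dF = 0.25, Ne = 1/(2*0.25)
        ped = make_pedigree_table({"A": (None, None), "B": (None, None),
                                   "C": ("A", "B"), "D": ("A", "B"),
                                   "E": ("C", "D"), "E2": ("C", "D")})
        cohort = az.Cohort("test", ("E", "E2"), 2.0, 2)
        ne_fi, ne_cij = az.ne_genealogical(ped, cohort)
        assert ne_fi == pytest.approx(2.0)
        # E,E2 full sibs of inbred parents: C = 0.375, dC = 1 - 0.625**(1/2)
        expected_dc = 1 - 0.625 ** 0.5
        assert ne_cij == pytest.approx(1 / (2 * expected_dc))

    def test_ne_undefined_for_founder_cohort(self):
        ped = make_pedigree_table({"A": (None, None), "B": (None, None)})
        cohort = az.Cohort("f", ("A", "B"), 0.0, 2)
        ne_fi, ne_cij = az.ne_genealogical(ped, cohort)
        assert math.isnan(ne_fi)
        assert math.isnan(ne_cij)
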