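"""Pedigree parsing and genealogical statistics.

The pedigree is a directed acyclic parent map.  From it we compute, per
individual: the inbreeding coefficient ``F`` (probability that the two
alleles at a locus are identical-by-descent), the number of fully traced
generations ``G``, the equivalent discrete generations ``t`` (sum of
``(1/2)**n`` over all known ancestors, ``n`` generations away), and the
individual increase in inbreeding ``dF = 1 - (1 - F)**(1/(t - 1))``.

Pairwise coancestry (kinship) coefficients and their per-generation
increases feed the two genealogical effective-population-size estimators

    Ne_Fi  = 1 / (2 * mean dF_i)        over cohort members
    Ne_Cij = 1 / (2 * mean dC_ij)       over within-cohort pairs

F is computed with the Meuwissen & Luo ancestor-tracing algorithm; the
full coancestry matrix with the tabular method.  Both agree with the
classical recursive kinship recursion (checked in the test suite).
"""

from __future__ import annotations

import heapq
import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = "0"

PEDIGREE_COLUMNS = (
    "id", "sire", "dam", "birth_year", "sex",
    "family_id", "litter_id", "genotyped", "is_bp",
)


class PedigreeError(ValueError):
    """Invalid pedigree structure (duplicate ids, cycles, bad references)."""


def _norm_id(value) -> str:
    """Normalize an id cell; empty/NA/'0'/'NA' parents collapse to UNKNOWN."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return UNKNOWN
    s = str(value).strip()
    if s == "" or s.lower() in ("0", "na", "nan", "none", "unknown", "."):
        return UNKNOWN
    # integers read back from CSV as floats ("12.0")
    if s.endswith(".0") and s[:-2].isdigit():
        s = s[:-2]
    return s


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    s = str(value).strip().lower()
    return s in ("1", "true", "t", "yes", "y", "1.0")


@dataclass
class Cohort:
    """A reference subpopulation: a labelled set of pedigree members."""

    label: str
    member_ids: tuple
    mean_t: float
    n: int

    def __post_init__(self):
        if self.n != len(self.member_ids) or self.n == 0:
            raise ValueError(f"cohort {self.label!r}: n must equal |member_ids| > 0")


@dataclass
class CoancestryPair:
    i: str
    j: str
    C: float
    dC: float = float("nan")


class PedigreeTable:
    """Validated pedigree with per-individual metadata.

    Parameters
    ----------
    df : DataFrame with at least columns id, sire, dam.  Optional columns:
        birth_year, sex, family_id, litter_id, genotyped (default True),
        is_bp (default False).  Unknown parents are "0"/empty/NA.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = {"id", "sire", "dam"} - set(df.columns)
        if missing:
            raise PedigreeError(f"pedigree is missing required columns: {sorted(missing)}")
        df["id"] = df["id"].map(_norm_id)
        df["sire"] = df["sire"].map(_norm_id)
        df["dam"] = df["dam"].map(_norm_id)
        if (df["id"] == UNKNOWN).any():
            raise PedigreeError("individual id may not be the unknown sentinel '0'")
        dup = df["id"][df["id"].duplicated()]
        if len(dup):
            raise PedigreeError(f"duplicate ids: {sorted(set(dup))}")
        for col, default in (("birth_year", np.nan), ("sex", ""), ("family_id", ""),
                             ("litter_id", ""), ("genotyped", True), ("is_bp", False)):
            if col not in df.columns:
                df[col] = default
        df["genotyped"] = df["genotyped"].map(_as_bool)
        df["is_bp"] = df["is_bp"].map(_as_bool)
        df["birth_year"] = pd.to_numeric(df["birth_year"], errors="coerce")
        df = df.reset_index(drop=True)

        known = set(df["id"])
        for col in ("sire", "dam"):
            bad = set(df[col]) - known - {UNKNOWN}
            if bad:
                # parents appearing only as parents become founder records
                extra = pd.DataFrame({"id": sorted(bad)})
                for c in df.columns:
                    if c not in extra.columns:
                        extra[c] = UNKNOWN if c in ("sire", "dam") else (
                            False if c in ("genotyped", "is_bp") else np.nan)
                df = pd.concat([df, extra], ignore_index=True)
                known |= bad

        self.df = df
        self._index = {iid: k for k, iid in enumerate(df["id"])}
        n = len(df)
        self.sire_idx = np.array(
            [self._index.get(s, -1) if s != UNKNOWN else -1 for s in df["sire"]], dtype=np.int64)
        self.dam_idx = np.array(
            [self._index.get(d, -1) if d != UNKNOWN else -1 for d in df["dam"]], dtype=np.int64)
        self.topo = self._topological_order()
        self._check_birth_years()
        self._n = n

    # -- structure ---------------------------------------------------------

    def _topological_order(self) -> np.ndarray:
        """Kahn's algorithm, parents before offspring; raises on cycles."""
        n = len(self.df)
        children = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=np.int64)
        for i in range(n):
            for p in (self.sire_idx[i], self.dam_idx[i]):
                if p >= 0:
                    children[p].append(i)
                    indeg[i] += 1
        queue = [i for i in range(n) if indeg[i] == 0]
        order = []
        while queue:
            i = queue.pop()
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) < n:
            cyc = self._find_cycle(children, indeg)
            raise PedigreeError("pedigree contains a cycle: " + " -> ".join(cyc))
        return np.array(order, dtype=np.int64)

    def _find_cycle(self, children, indeg) -> list:
        # nodes still holding in-degree after Kahn's pass all lie on or above
        # a cycle; walking parents inside that set must revisit a node
        ids = list(self.df["id"])
        remaining = {i for i in range(len(ids)) if indeg[i] > 0}
        node = next(iter(remaining))
        seen, chain = {}, []
        while node not in seen:
            seen[node] = len(chain)
            chain.append(node)
            node = next(p for p in (self.sire_idx[node], self.dam_idx[node])
                        if p in remaining)
        loop = chain[seen[node]:] + [node]
        return [ids[i] for i in loop]

    def _check_birth_years(self):
        by = self.df["birth_year"].to_numpy(dtype=float)
        for i in range(len(by)):
            for p in (self.sire_idx[i], self.dam_idx[i]):
                if p >= 0 and np.isfinite(by[i]) and np.isfinite(by[p]) and by[i] < by[p]:
                    raise PedigreeError(
                        f"{self.df['id'][i]} born {int(by[i])} before parent "
                        f"{self.df['id'][p]} ({int(by[p])})")

    # -- accessors ---------------------------------------------------------

    def __len__(self):
        return self._n

    def __contains__(self, iid):
        return iid in self._index

    @property
    def ids(self) -> list:
        return list(self.df["id"])

    def index_of(self, iid: str) -> int:
        return self._index[iid]

    def founders(self) -> list:
        mask = (self.sire_idx < 0) & (self.dam_idx < 0)
        return [iid for iid, m in zip(self.ids, mask) if m]

    def genotyped_ids(self) -> list:
        return list(self.df.loc[self.df["genotyped"], "id"])

    def bp_ids(self) -> list:
        return list(self.df.loc[self.df["is_bp"], "id"])

    def parents_of(self, iid: str) -> tuple:
        k = self._index[iid]
        s, d = self.sire_idx[k], self.dam_idx[k]
        ids = self.ids
        return (ids[s] if s >= 0 else None, ids[d] if d >= 0 else None)


def load_pedigree(path) -> PedigreeTable:
    """Read a pedigree CSV (columns id,sire,dam[,birth_year,sex,...])."""
    df = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str})
    return PedigreeTable(df)


# ---------------------------------------------------------------------------
# inbreeding and kinship
# ---------------------------------------------------------------------------

def inbreeding_meuwissen_luo(ped: PedigreeTable) -> dict:
    """Inbreeding coefficients by the Meuwissen & Luo tracing algorithm.

    For individual i with both parents known, F_i = A_ii - 1 where
    A_ii = sum_j L_ij^2 D_j over ancestors j (including i), with
    D_j = 0.5 - 0.25 (F_sire(j) + F_dam(j)) and the F of an unknown parent
    taken as -1.  Ancestors are visited youngest-first so each contributes
    a single coalesced path coefficient.
    """
    n = len(ped)
    F = np.zeros(n)
    D = np.zeros(n)
    sire, dam = ped.sire_idx, ped.dam_idx
    topo_pos = np.empty(n, dtype=np.int64)
    topo_pos[ped.topo] = np.arange(n)

    for i in ped.topo:
        fs = F[sire[i]] if sire[i] >= 0 else -1.0
        fd = F[dam[i]] if dam[i] >= 0 else -1.0
        D[i] = 0.5 - 0.25 * (fs + fd)
        if sire[i] < 0 or dam[i] < 0:
            F[i] = 0.0
            continue
        coeff = {i: 1.0}
        heap = [-topo_pos[i]]
        aii = 0.0
        while heap:
            j = ped.topo[-heapq.heappop(heap)]
            if j not in coeff:
                continue
            v = coeff.pop(j)
            aii += v * v * D[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    if p not in coeff:
                        coeff[p] = 0.0
                        heapq.heappush(heap, -topo_pos[p])
                    coeff[p] += 0.5 * v
        F[i] = aii - 1.0
    return dict(zip(ped.ids, F.tolist()))


def kinship_matrix(ped: PedigreeTable) -> pd.DataFrame:
    """Full coancestry (kinship) matrix by the tabular method.

    f_ii = 0.5 (1 + f_sd);  f_ij = 0.5 (f_sj + f_dj) for j older than i.
    """
    n = len(ped)
    order = ped.topo
    pos = np.empty(n, dtype=np.int64)
    pos[order] = np.arange(n)
    sire, dam = ped.sire_idx, ped.dam_idx
    K = np.zeros((n, n))  # indexed by topological position
    for r, i in enumerate(order):
        s, d = sire[i], dam[i]
        row = np.zeros(r)
        if s >= 0:
            row += K[pos[s], :r]
        if d >= 0:
            row += K[pos[d], :r]
        row *= 0.5
        K[r, :r] = row
        K[:r, r] = row
        fsd = K[pos[s], pos[d]] if (s >= 0 and d >= 0) else 0.0
        K[r, r] = 0.5 * (1.0 + fsd)
    ids_in_topo = [ped.ids[i] for i in order]
    out = pd.DataFrame(K, index=ids_in_topo, columns=ids_in_topo)
    return out.loc[ped.ids, ped.ids]


def coancestry(ped: PedigreeTable, pairs) -> list:
    """Coancestry coefficients for the requested id pairs."""
    K = kinship_matrix(ped)
    t = {iid: gt for iid, gt in equivalent_generations(ped).items()}
    out = []
    for i, j in pairs:
        if i not in ped or j not in ped:
            raise PedigreeError(f"unknown individual in pair ({i}, {j})")
        C = float(K.loc[i, j])
        dc = delta_C_pairwise(C, t[i][1], t[j][1])
        out.append(CoancestryPair(i=i, j=j, C=C, dC=dc))
    return out


# ---------------------------------------------------------------------------
# pedigree depth
# ---------------------------------------------------------------------------

def equivalent_generations(ped: PedigreeTable) -> dict:
    """Per individual: (G, t).

    t = sum over known ancestors of (1/2)^n, computed by the recursion
    t_i = sum over known parents p of 0.5 * (1 + t_p).
    G = number of fully traced generations: 0 if any parent is unknown,
    else 1 + min(G_sire, G_dam).
    """
    n = len(ped)
    t = np.zeros(n)
    G = np.zeros(n, dtype=np.int64)
    sire, dam = ped.sire_idx, ped.dam_idx
    for i in ped.topo:
        s, d = sire[i], dam[i]
        ti = 0.0
        if s >= 0:
            ti += 0.5 * (1.0 + t[s])
        if d >= 0:
            ti += 0.5 * (1.0 + t[d])
        t[i] = ti
        G[i] = 1 + min(G[s], G[d]) if (s >= 0 and d >= 0) else 0
    return {iid: (int(g), float(tv)) for iid, g, tv in zip(ped.ids, G, t)}


def delta_F_individual(F: float, t: float) -> float:
    """Individual increase in inbreeding, 1 - (1-F)**(1/(t-1)).

    Undefined (NaN) when t <= 1: the exponent is singular at t = 1 and an
    individual with no traced generations carries no rate information.
    """
    if not (0.0 <= F < 1.0):
        return float("nan")
    if t <= 1.0:
        return float("nan")
    return 1.0 - (1.0 - F) ** (1.0 / (t - 1.0))


def delta_C_pairwise(C: float, ti: float, tj: float) -> float:
    """Increase in pairwise coancestry, 1 - (1-C)**(2/(ti+tj))."""
    if not (0.0 <= C < 1.0):
        return float("nan")
    if ti + tj <= 0.0:
        return float("nan")
    return 1.0 - (1.0 - C) ** (2.0 / (ti + tj))


def genealogy_table(ped: PedigreeTable) -> pd.DataFrame:
    """Per-individual F, G, t and dF as one DataFrame (index = id)."""
    F = inbreeding_meuwissen_luo(ped)
    gt = equivalent_generations(ped)
    rows = {iid: (F[iid], gt[iid][0], gt[iid][1],
                  delta_F_individual(F[iid], gt[iid][1])) for iid in ped.ids}
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["F", "G", "t", "dF"])
    out.index.name = "id"
    return out


# ---------------------------------------------------------------------------
# cohorts and genealogical Ne
# ---------------------------------------------------------------------------

def define_cohorts(ped: PedigreeTable, scheme: str, *, merge_years=None,
                   t_threshold: float = 2.0, genotyped_only: bool = True) -> list:
    """Build reference subpopulations.

    scheme='year': one cohort per birth year (label 'C<year>'); the
        merge_years mapping (e.g. {2010: 2009}) absorbs sparse years.
    scheme='complete_generations': one cohort per G value >= 1 ('CG<g>').
    scheme='t_threshold': single cohort of individuals with t >= threshold.
    """
    gt = equivalent_generations(ped)
    df = ped.df
    pool = df[df["genotyped"]] if genotyped_only else df
    cohorts = []
    if scheme == "year":
        merge_years = merge_years or {}
        years = pool["birth_year"].dropna().astype(int).map(lambda y: merge_years.get(y, y))
        for year in sorted(years.unique()):
            ids = tuple(pool.loc[years.index[years == year], "id"])
            ts = [gt[i][1] for i in ids]
            cohorts.append(Cohort(f"C{year}", ids, float(np.mean(ts)), len(ids)))
    elif scheme == "complete_generations":
        gvals = pool["id"].map(lambda i: gt[i][0])
        for g in sorted(gvals.unique()):
            if g < 1:
                continue
            ids = tuple(pool.loc[gvals.index[gvals == g], "id"])
            ts = [gt[i][1] for i in ids]
            cohorts.append(Cohort(f"CG{g}", ids, float(np.mean(ts)), len(ids)))
    elif scheme == "t_threshold":
        ids = tuple(i for i in pool["id"] if gt[i][1] >= t_threshold)
        if ids:
            ts = [gt[i][1] for i in ids]
            cohorts.append(Cohort("t-subset", ids, float(np.mean(ts)), len(ids)))
    else:
        raise ValueError(f"unknown cohort scheme {scheme!r}")
    if not cohorts:
        warnings.warn(f"no individuals matched cohort scheme {scheme!r}")
    return cohorts


def ne_genealogical(ped: PedigreeTable, cohort: Cohort, *,
                    genealogy: pd.DataFrame | None = None,
                    kinship: pd.DataFrame | None = None) -> tuple:
    """(Ne_Fi, Ne_Cij) for a cohort.

    Ne_Fi averages dF_i over members with defined dF; Ne_Cij averages
    dC_ij over all unordered within-cohort pairs.  A non-positive mean
    increase yields +inf (no measurable loss of diversity); no defined
    increments yield NaN.
    """
    gen = genealogy if genealogy is not None else genealogy_table(ped)
    K = kinship if kinship is not None else kinship_matrix(ped)
    ids = list(cohort.member_ids)

    dfs = gen.loc[ids, "dF"].to_numpy(dtype=float)
    dfs = dfs[np.isfinite(dfs)]
    if dfs.size == 0:
        ne_fi = float("nan")
    else:
        m = dfs.mean()
        ne_fi = float("inf") if m <= 0 else 1.0 / (2.0 * m)

    tvals = gen.loc[ids, "t"].to_numpy(dtype=float)
    sub = K.loc[ids, ids].to_numpy()
    iu, ju = np.triu_indices(len(ids), k=1)
    if iu.size == 0:
        return ne_fi, float("nan")
    C = sub[iu, ju]
    texp = (tvals[iu] + tvals[ju]) / 2.0
    ok = (texp > 0) & (C < 1.0) & (C >= 0.0)
    dC = 1.0 - (1.0 - C[ok]) ** (1.0 / texp[ok])
    if dC.size == 0:
        ne_cij = float("nan")
    else:
        m = dC.mean()
        ne_cij = float("inf") if m <= 0 else 1.0 / (2.0 * m)
    return ne_fi, ne_cij
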