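"""Increases in genomic homozygosity, genomic Ne, and RMSE comparisons.

Two per-individual rates are derived from an adjusted homozygosity value
F (BP-adjusted or jackknifed, possibly negative):

    dtF = 1 - (1 - F)**(1/t)            individual increase (note the
                                        exponent t, not t-1: the genomic
                                        zero point is the BP, not the
                                        parents' generation)
    dpF = (F_off - Fp) / (1 - Fp)       pairwise increase over the
                                        parental mean Fp

Cohort effective sizes follow as Ne = 1 / (2 * mean rate), and each
genomic Ne series over the five study cohorts is compared with the
genealogical references (Ne_Fi and Ne_Cij) by root-mean-squared error.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .adjust import ESTIMATORS
from .pedigree import Cohort, PedigreeTable

BASES = ("bp_adjusted", "jackknifed")
APPROACHES = ("individual", "pairwise")


def delta_t_homozygosity(F: float, t: float) -> float:
    """Individual increase in homozygosity, 1 - (1-F)**(1/t); NaN if t <= 0
    or F >= 1.  Negative adjusted F passes through (rate is negative)."""
    if not np.isfinite(F) or F >= 1.0 or t <= 0.0:
        return float("nan")
    return 1.0 - (1.0 - F) ** (1.0 / t)


def delta_p_homozygosity(F_off: float, F_sire: float, F_dam: float) -> float:
    """Pairwise increase over the parental mean; NaN if a parent value is
    missing or the parental mean reaches 1."""
    if not (np.isfinite(F_off) and np.isfinite(F_sire) and np.isfinite(F_dam)):
        return float("nan")
    parent_mean = 0.5 * (F_sire + F_dam)
    if parent_mean >= 1.0:
        return float("nan")
    return (F_off - parent_mean) / (1.0 - parent_mean)


def increment_table(adjusted: pd.DataFrame, ped: PedigreeTable,
                    genealogy: pd.DataFrame) -> pd.DataFrame:
    """Per-individual dtF and dpF for every estimator and basis.

    dtF uses the individual's equivalent discrete generations t; dpF needs
    both parents present in the adjusted table (undefined otherwise, and
    excluded from cohort means rather than zero-filled).

    Returns a DataFrame indexed by individual, MultiIndex columns
    (estimator, basis, {'dtF', 'dpF'}).
    """
    ids = list(adjusted.index)
    t = genealogy["t"]
    estimators = [e for e in ESTIMATORS if e in adjusted.columns.get_level_values(0)]
    out = {}
    for est in estimators:
        for basis in BASES:
            if (est, basis) not in adjusted.columns:
                continue
            F = adjusted[(est, basis)]
            dt = np.array([delta_t_homozygosity(F[i], float(t.loc[i])) for i in ids])
            dp = np.empty(len(ids))
            for k, iid in enumerate(ids):
                sire, dam = ped.parents_of(iid)
                if sire in adjusted.index and dam in adjusted.index:
                    dp[k] = delta_p_homozygosity(F[iid], F[sire], F[dam])
                else:
                    dp[k] = float("nan")
            out[(est, basis, "dtF")] = dt
            out[(est, basis, "dpF")] = dp
    table = pd.DataFrame(out, index=pd.Index(ids, name="id"))
    table.columns = pd.MultiIndex.from_tuples(
        table.columns, names=["estimator", "basis", "rate"])
    return table


def ne_from_mean_rate(mean_rate: float) -> float:
    if not np.isfinite(mean_rate):
        return float("nan")
    if mean_rate <= 0.0:
        return float("inf")
    return 1.0 / (2.0 * mean_rate)


def ne_genomic(increments: pd.DataFrame, cohort: Cohort, estimator: str,
               basis: str, approach: str) -> float:
    """1 / (2 * mean defined increment) over cohort members.

    approach='individual' averages dtF; 'pairwise' averages dpF.
    Undefined increments are excluded; a non-positive mean yields +inf.
    """
    rate = {"individual": "dtF", "pairwise": "dpF"}[approach]
    ids = [i for i in cohort.member_ids if i in increments.index]
    vals = increments.loc[ids, (estimator, basis, rate)].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return ne_from_mean_rate(float(vals.mean()))


def ne_report(increments: pd.DataFrame, cohorts, genealogical_ne: dict) -> pd.DataFrame:
    """Cohorts x methods Ne table (the study's Table-2 layout).

    genealogical_ne maps cohort label -> (Ne_Fi, Ne_Cij).
    """
    estimators = sorted({c[0] for c in increments.columns})
    rows = []
    for cohort in cohorts:
        row = {("cohort", "", "n"): cohort.n, ("cohort", "", "mean_t"): cohort.mean_t,
               ("genealogical", "", "Ne_Fi"): genealogical_ne[cohort.label][0],
               ("genealogical", "", "Ne_Cij"): genealogical_ne[cohort.label][1]}
        for est in ESTIMATORS:
            if est not in estimators:
                continue
            for basis in BASES:
                for approach in APPROACHES:
                    if (est, basis, {"individual": "dtF", "pairwise": "dpF"}[approach]) \
                            not in increments.columns:
                        continue
                    row[(est, basis, approach)] = ne_genomic(
                        increments, cohort, est, basis, approach)
        rows.append(pd.Series(row, name=cohort.label))
    out = pd.DataFrame(rows)
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["estimator", "basis", "value"])
    out.index.name = "cohort"
    return out


def rmse_vs_reference(ne_genomic_values, ne_reference_values) -> float:
    """sqrt(mean squared difference) over paired cohort Ne values."""
    est = np.asarray(ne_genomic_values, dtype=float)
    ref = np.asarray(ne_reference_values, dtype=float)
    if est.shape != ref.shape or est.size == 0:
        raise ValueError("paired vectors of equal positive length required")
    if not (np.isfinite(est).all() and np.isfinite(ref).all()):
        raise ValueError("undefined Ne in RMSE input")
    return float(math.sqrt(np.mean((ref - est) ** 2)))


def rmse_table(report: pd.DataFrame) -> pd.DataFrame:
    """RMSE of every genomic Ne series against both genealogical references.

    Rows: (approach, estimator); columns: (reference, basis) -- the
    study's Table-3 2x2 layout.
    """
    refs = {"Ne_Fi": report[("genealogical", "", "Ne_Fi")].to_numpy(),
            "Ne_Cij": report[("genealogical", "", "Ne_Cij")].to_numpy()}
    estimators = [e for e in ESTIMATORS
                  if e in report.columns.get_level_values(0)]
    rows = {}
    for approach in APPROACHES:
        for est in estimators:
            row = {}
            for ref_name, ref in refs.items():
                for basis in BASES:
                    if (est, basis, approach) not in report.columns:
                        continue
                    series = report[(est, basis, approach)].to_numpy(dtype=float)
                    row[(ref_name, basis)] = rmse_vs_reference(series, ref)
            if row:
                rows[(approach, est)] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index = pd.MultiIndex.from_tuples(rows.keys(), names=["approach", "estimator"])
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["reference", "basis"])
    return out
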