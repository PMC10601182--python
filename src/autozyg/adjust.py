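"""Base-population adjustment and delete-one jackknifing over autosomes.

Raw homozygosity estimates are first centred on the base population (BP):

    F_ia = (F_i - F_BP) / (1 - F_BP)

where F_BP is the mean of the same estimator over BP members.  Adjusted
values may be negative and are never truncated.

The per-autosome BP-adjusted values (each autosome centred on its own BP
mean) are then combined per individual with a delete-one jackknife in the
bias-corrected pseudo-value (Quenouille/Tukey) form: with theta_all the
(weighted) mean over the n autosomes and theta_(-c) the mean excluding
autosome c,

    pseudo_c = n * theta_all - (n - 1) * theta_(-c)
    estimate = mean(pseudo),  se = sd(pseudo) / sqrt(n).

Unweighted by default (pseudo-values then reduce to the per-autosome
values themselves); SNP-count or length weights are an option.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .estimators import GENOME

ESTIMATORS = ("F_ROH", "F_HRR", "F_LH", "F_YAN")


def bp_adjust(F_i, F_BP: float):
    """Powell-style BP adjustment (F_i - F_BP) / (1 - F_BP); vectorized.

    Undefined (NaN) when F_BP >= 1: a fully homozygous base population
    leaves no heterozygosity to lose.
    """
    if not np.isfinite(F_BP) or F_BP >= 1.0:
        warnings.warn(f"F_BP = {F_BP}: adjustment undefined, returning NaN")
        return np.full(np.shape(F_i), np.nan) if np.ndim(F_i) else float("nan")
    return (np.asarray(F_i, dtype=float) - F_BP) / (1.0 - F_BP) \
        if np.ndim(F_i) else (float(F_i) - F_BP) / (1.0 - F_BP)


def jackknife_autosomes(per_chrom_values, weights=None) -> tuple:
    """Delete-one jackknife over autosomes -> (estimate, se).

    NaN chromosome values are dropped with a warning (n reduced).
    """
    vals = np.asarray(per_chrom_values, dtype=float)
    w = np.ones_like(vals) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != vals.shape:
        raise ValueError("weights must match values")
    ok = np.isfinite(vals)
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} undefined chromosome values "
                      "from the jackknife")
        vals, w = vals[ok], w[ok]
    n = vals.size
    if n < 2:
        raise ValueError("jackknife needs >= 2 defined chromosome values")
    total_w = w.sum()
    theta_all = float(np.sum(w * vals) / total_w)
    loo = (np.sum(w * vals) - w * vals) / (total_w - w)  # theta_(-c)
    pseudo = n * theta_all - (n - 1) * loo
    estimate = float(pseudo.mean())
    se = float(pseudo.std(ddof=1) / np.sqrt(n))
    return estimate, se


def bp_means(raw: pd.DataFrame, bp_member_ids) -> pd.DataFrame:
    """Mean raw value over BP members, per (estimator, scope).

    BP members with an undefined estimator value in a scope are dropped
    from that mean with a warning.
    """
    members = [str(i) for i in bp_member_ids]
    sub = raw.loc[[m for m in members if m in raw.index]]
    if len(sub) < len(members):
        missing = set(members) - set(sub.index)
        warnings.warn(f"BP members absent from the raw table: {sorted(missing)}")
    if sub.isna().any().any():
        warnings.warn("BP members with undefined values dropped from some BP means")
    return sub.mean(axis=0, skipna=True).unstack(level=-1)


def adjust_pipeline(raw: pd.DataFrame, bp_member_ids, *, weights=None) -> pd.DataFrame:
    """BP-adjust genome-wide and per autosome, then jackknife per individual.

    Parameters
    ----------
    raw : homozygosity table from ``estimators.homozygosity_table``
        (MultiIndex columns (estimator, scope)).
    bp_member_ids : ids defining the base population.
    weights : optional per-chromosome weights (dict scope -> weight) for
        the weighted jackknife.

    Returns a DataFrame indexed by individual with MultiIndex columns
    (estimator, {'bp_adjusted', 'jackknifed', 'jackknife_se'}).
    """
    means = bp_means(raw, bp_member_ids)
    scopes = [s for s in raw.columns.levels[1] if s != GENOME]
    w = None if weights is None else np.array([weights[s] for s in scopes], dtype=float)

    out = {}
    for est in ESTIMATORS:
        if est not in raw.columns.levels[0]:
            continue
        f_bp = float(means.loc[est, GENOME])
        out[(est, "bp_adjusted")] = bp_adjust(raw[(est, GENOME)].to_numpy(), f_bp)
        per_chrom = raw[est][scopes].to_numpy(dtype=float)
        chrom_bp = means.loc[est, scopes].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            adj = np.where(chrom_bp < 1.0,
                           (per_chrom - chrom_bp) / (1.0 - chrom_bp), np.nan)
        jk = np.empty(len(raw.index))
        jk_se = np.empty(len(raw.index))
        for k in range(len(raw.index)):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    jk[k], jk_se[k] = jackknife_autosomes(adj[k], weights=w)
            except ValueError:
                jk[k] = jk_se[k] = float("nan")
        out[(est, "jackknifed")] = jk
        out[(est, "jackknife_se")] = jk_se

    table = pd.DataFrame(out, index=raw.index)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["estimator", "value"])
    return table
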