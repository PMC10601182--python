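"""File formats, run manifests, and the supplementary-table replay.

Formats handled here:
  * pedigree CSV (delegated to :mod:`autozyg.pedigree`),
  * PLINK-style text PED/MAP with deterministic biallelic recoding
    (the lexicographically smaller allele label becomes the reference
    counted by the 0/1/2 codes; "0 0" is missing),
  * TSV reports with flattened multi-level headers and a manifest
    digest comment line,
  * BED (0-based half-open) for merged ROH/HRR regions,
  * spreadsheet / delimited sheets of per-individual values for the
    replay pipeline, which re-runs the genealogical, adjustment,
    increment, Ne and RMSE stages from deposited values, bypassing the
    genotype-level stages.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adjust import ESTIMATORS, bp_adjust, bp_means
from .estimators import GENOME
from .increments import increment_table, ne_report, rmse_table
from .pedigree import (PedigreeTable, define_cohorts, genealogy_table,
                       kinship_matrix, ne_genealogical)
from .runs import MISSING, GenotypeMatrix, MarkerMap


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# PLINK PED/MAP
# ---------------------------------------------------------------------------

def read_ped_map(ped_path, map_path, ref_alleles=None):
    """Read text PED/MAP into (GenotypeMatrix, MarkerMap, recode table).

    Alleles are recoded to counts of a deterministically chosen reference
    allele: the lexicographically smaller of the (at most two) allele
    labels seen at the SNP.  The recode table records the choice per SNP.
    A SNP where only the alternate allele was observed cannot reveal the
    original reference label; pass ``ref_alleles`` (mapping SNP name ->
    allele, e.g. a previous recode table) to pin the coding exactly.
    """
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (3, 4):
                raise FormatError(f"{map_path}:{lineno}: expected 3 or 4 columns")
            chrom, name = parts[0], parts[1]
            pos = int(parts[-1])
            rows.append((name, chrom, pos))
    mdf = pd.DataFrame(rows, columns=["name", "chrom", "pos_bp"])
    marker_map = MarkerMap(mdf)
    n_snps = len(marker_map)

    ids, tokens = [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise FormatError(
                    f"{ped_path}:{lineno}: ragged row, expected {6 + 2 * n_snps} "
                    f"fields, got {len(parts)}")
            ids.append(parts[1])
            tokens.append(parts[6:])
    alleles = np.array(tokens, dtype="U8").reshape(len(ids), n_snps, 2)

    matrix = np.full((len(ids), n_snps), MISSING, dtype=np.int8)
    recode = []
    names = marker_map.df["name"]
    for k in range(n_snps):
        pair = alleles[:, k, :]
        seen = sorted(set(np.unique(pair)) - {"0"})
        if len(seen) > 2:
            raise FormatError(f"SNP {names[k]} has >2 alleles: {seen}")
        if ref_alleles is not None and names[k] in ref_alleles:
            ref = ref_alleles[names[k]]
        else:
            ref = seen[0] if seen else "0"
        missing = (pair == "0").any(axis=1)
        matrix[:, k] = np.where(missing, MISSING, (pair == ref).sum(axis=1))
        recode.append((names[k], ref, seen[-1] if len(seen) > 1 else ""))
    geno = GenotypeMatrix(ids, matrix)
    recode_df = pd.DataFrame(recode, columns=["name", "ref_allele", "alt_allele"])
    return geno, marker_map, recode_df


def write_ped_map(geno: GenotypeMatrix, marker_map: MarkerMap, ped_path, map_path,
                  pedigree: PedigreeTable | None = None):
    """Write text PED/MAP; reference allele 'A', alternate 'B' (so a
    round trip through read_ped_map preserves the 0/1/2 coding)."""
    with open(map_path, "w") as fh:
        for _, row in marker_map.df.iterrows():
            fh.write(f"{row['chrom']}\t{row['name']}\t0\t{row['pos_bp']}\n")
    code = {2: "A A", 1: "A B", 0: "B B", MISSING: "0 0"}
    sex_code = {"M": "1", "F": "2"}
    with open(ped_path, "w") as fh:
        for iid in geno.ids:
            sire = dam = "0"
            fid, sx = iid, "0"
            if pedigree is not None and iid in pedigree:
                s, d = pedigree.parents_of(iid)
                sire, dam = s or "0", d or "0"
                rec = pedigree.df.iloc[pedigree.index_of(iid)]
                fid = rec["family_id"] or iid
                sx = sex_code.get(str(rec["sex"]).upper()[:1], "0")
            gstr = " ".join(code[int(x)] for x in geno.vector(iid))
            fh.write(f"{fid} {iid} {sire} {dam} {sx} -9 {gstr}\n")


# ---------------------------------------------------------------------------
# TSV tables and BED
# ---------------------------------------------------------------------------

_COL_SEP = "|"


def write_table(df: pd.DataFrame, path, digest: str = ""):
    """TSV with multi-level columns flattened as 'a|b|c' and a comment
    header carrying the manifest digest."""
    out = df.copy()
    if isinstance(out.columns, pd.MultiIndex):
        out.columns = [_COL_SEP.join(str(p) for p in tup if str(p) != "")
                       for tup in out.columns]
    if isinstance(out.index, pd.MultiIndex):
        out = out.reset_index()
    with open(path, "w") as fh:
        fh.write(f"# autozyg {__version__} manifest={digest}\n")
        out.to_csv(fh, sep="\t")


def read_table(path, levels: int = 1, index_col=0) -> pd.DataFrame:
    """Read a TSV written by write_table, restoring multi-level columns."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
    df.index = df.index.astype(str)
    if levels > 1:
        tuples = []
        for c in df.columns:
            parts = str(c).split(_COL_SEP)
            parts += [""] * (levels - len(parts))
            tuples.append(tuple(parts))
        df.columns = pd.MultiIndex.from_tuples(tuples)
    return df


def write_runs_tsv(segments, path, digest: str = ""):
    rows = [(s.individual, s.chrom, s.start_bp, s.end_bp, s.n_snps, s.kind)
            for s in segments]
    df = pd.DataFrame(rows, columns=["id", "chrom", "start_bp", "end_bp",
                                     "n_snps", "kind"]).set_index("id")
    write_table(df, path, digest)


def write_bed(regions: pd.DataFrame, path):
    """Merged regions as BED: 1-based inclusive -> 0-based half-open;
    the score column carries n_individuals."""
    with open(path, "w") as fh:
        for k, row in enumerate(regions.itertuples(index=False)):
            fh.write(f"{row.chrom}\t{row.start_bp - 1}\t{row.end_bp}\t"
                     f"region{k + 1}\t{row.n_individuals}\n")


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    version: str
    seed: int | None
    created: str
    config: dict
    inputs: dict  # path -> sha256

    @property
    def digest(self) -> str:
        payload = json.dumps({"config": self.config, "inputs": self.inputs},
                             sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def make_manifest(config: dict, inputs, seed=None) -> RunManifest:
    return RunManifest(
        version=__version__, seed=seed,
        created=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        config={k: (str(v) if isinstance(v, Path) else v) for k, v in config.items()},
        inputs={str(p): file_digest(p) for p in inputs},
    )


def write_manifest(manifest: RunManifest, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = asdict(manifest)
    data["digest"] = manifest.digest
    (outdir / "manifest.json").write_text(json.dumps(data, indent=2) + "\n")
    return manifest.digest


# ---------------------------------------------------------------------------
# supplementary replay
# ---------------------------------------------------------------------------

S1_COLUMNS = ("id", "sire", "dam", "birth_year", "is_bp",
              "F_ROH", "F_HRR", "F_LH", "F_YAN")


def read_sheet(source, column_map: dict | None = None, sheet=0) -> pd.DataFrame:
    """Load a per-individual sheet (.xlsx/.csv/.tsv or DataFrame) and
    rename columns via column_map (canonical name -> column in file)."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        path = Path(source)
        if path.suffix.lower() in (".xlsx", ".xls"):
            df = pd.read_excel(path, sheet_name=sheet)
        else:
            sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
            df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return df


def _require(df: pd.DataFrame, cols, what: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required columns {missing}; "
                          f"available: {list(df.columns)}")


def replay_supplementary(s1, s2=None, s4=None, *, column_map=None,
                         merge_years=None, t_threshold: float = 2.0,
                         cohort_labels=None) -> dict:
    """Re-run the genealogical / adjustment / increment / Ne / RMSE stages
    from per-individual deposited values (S1 raw, S2 BP-adjusted, S4
    jackknifed sheets), bypassing genotype-level computation.

    Reference cohorts default to birth-year cohorts with mean t >= 2
    plus the complete-generation cohorts CG2/CG3 (per-generation rates
    are meaningless in founder-year cohorts); pass ``cohort_labels`` to
    select explicitly.

    Returns a dict with the genealogy table, cohort list, per-basis
    summaries, the cohorts-by-methods Ne table and the RMSE table.
    """
    merge_years = {2010: 2009} if merge_years is None else merge_years
    cmap = column_map or {}
    s1 = read_sheet(s1, cmap.get("s1"))
    _require(s1, ("id", "sire", "dam"), "S1 sheet")
    estimators = [e for e in ESTIMATORS if e in s1.columns]

    ped = PedigreeTable(s1)
    geneal = genealogy_table(ped)
    kin = kinship_matrix(ped)
    gids = ped.genotyped_ids()

    cohorts = (define_cohorts(ped, "year", merge_years=merge_years)
               + define_cohorts(ped, "complete_generations"))
    if cohort_labels is not None:
        cohorts = [c for c in cohorts if c.label in set(cohort_labels)]
    else:
        cohorts = [c for c in cohorts
                   if (c.label.startswith("CG") and c.label in ("CG2", "CG3"))
                   or (not c.label.startswith("CG") and c.mean_t >= 2.0)]
    t_subset = define_cohorts(ped, "t_threshold", t_threshold=t_threshold)

    geneal_ne = {c.label: ne_genealogical(ped, c, genealogy=geneal, kinship=kin)
                 for c in cohorts}

    raw = s1.set_index(s1["id"].astype(str))[estimators].astype(float)
    summary = {
        "n_genotyped": len(gids),
        "n_noninbred": int((geneal.loc[gids, "F"] < 1e-12).sum()),
        "mean_F": float(geneal.loc[gids, "F"].mean()),
        "mean_t": float(geneal.loc[gids, "t"].mean()),
        "mean_dF": float(np.nanmean(geneal.loc[gids, "dF"].to_numpy(dtype=float))),
        "t_subset_n": t_subset[0].n if t_subset else 0,
        "negative_raw": {e: int((raw[e] < 0).sum()) for e in estimators},
        "raw_means": {e: float(raw[e].mean()) for e in estimators},
    }

    # adjusted values: prefer deposited S2/S4 sheets, else BP-adjust raw
    adjusted = {}
    if s2 is not None:
        s2 = read_sheet(s2, cmap.get("s2")).set_index("id")
        s2.index = s2.index.astype(str)
        _require(s2, estimators, "S2 sheet")
        for e in estimators:
            adjusted[(e, "bp_adjusted")] = s2[e].astype(float)
    elif ped.bp_ids():
        rawcols = pd.DataFrame({(e, GENOME): raw[e] for e in estimators})
        rawcols.columns = pd.MultiIndex.from_tuples(
            rawcols.columns, names=["estimator", "scope"])
        means = bp_means(rawcols, ped.bp_ids())
        for e in estimators:
            adjusted[(e, "bp_adjusted")] = pd.Series(
                bp_adjust(raw[e].to_numpy(), float(means.loc[e, GENOME])), index=raw.index)
    if s4 is not None:
        s4 = read_sheet(s4, cmap.get("s4")).set_index("id")
        s4.index = s4.index.astype(str)
        _require(s4, estimators, "S4 sheet")
        for e in estimators:
            adjusted[(e, "jackknifed")] = s4[e].astype(float)

    out = {"pedigree": ped, "genealogy": geneal, "cohorts": cohorts,
           "genealogical_ne": geneal_ne, "summary": summary}
    if adjusted:
        adj = pd.DataFrame(adjusted)
        adj.columns = pd.MultiIndex.from_tuples(adj.columns,
                                                names=["estimator", "basis"])
        incr = increment_table(adj, ped, geneal)
        out["adjusted"] = adj
        out["increments"] = incr
        out["summary"]["mean_bp_adjusted"] = {
            e: float(adj[(e, "bp_adjusted")].mean()) for e in estimators
            if (e, "bp_adjusted") in adj.columns}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out["summary"]["mean_increments"] = {
                (e, b, r): float(np.nanmean(incr[(e, b, r)].to_numpy(dtype=float)))
                for (e, b, r) in incr.columns}
        if cohorts:
            report = ne_report(incr, cohorts, geneal_ne)
            out["ne_table"] = report
            try:
                out["rmse_table"] = rmse_table(report)
            except (ValueError, KeyError) as exc:
                warnings.warn(f"RMSE not computed: {exc}")
    return out
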