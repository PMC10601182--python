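"""Gene-dropping synthetic data: pedigrees plus SNP genotypes with truth.

The generator emulates a small conserved livestock population: a handful
of founders (default 6), up to four discrete generations, large full-sib
families, and a minimum-coancestry mating policy (no matings between
pairs with kinship >= 0.125).  Genotypes arise by dropping labelled
founder alleles down the pedigree with Haldane recombination (Poisson
crossover count in map length, uniform placement, no interference), so
the realized identity-by-descent fraction of every individual is known
exactly per SNP and serves as the recovery target for every downstream
estimator.

Founder minor-allele frequencies are drawn from a symmetric Beta
(default Beta(0.8, 0.8), an array-like U-shaped site-frequency spectrum)
and a configured fraction of sites is forced monomorphic, mimicking
array content.  All randomness flows from one mandatory seed; identical
configurations are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import PedigreeTable
from .runs import MISSING, GenotypeMatrix, MarkerMap

RANDOM = "random"
AVOID_CLOSE = "avoid_close_relatives"
FULL_SIB_BURST = "full_sib_burst"

CLOSE_KINSHIP = 0.125  # matings at or above this coancestry are prohibited


@dataclass
class SimConfig:
    """Study-condition defaults: 6 founders, 18 autosomes, 30% monomorphic
    sites, litters up to 34, minimum-coancestry matings."""

    seed: int
    n_founders: int = 6
    n_generations: int = 4
    mating_policy: str = AVOID_CLOSE
    n_matings_per_generation: int = 8
    litter_mean: float = 8.0
    litter_max: int = 34
    n_autosomes: int = 18
    snps_per_autosome: int = 2_000
    chrom_length_bp: int = 100_000_000
    chrom_length_morgans: float = 1.0
    founder_maf_beta: tuple = (0.8, 0.8)
    monomorphic_fraction: float = 0.30
    missing_rate: float = 0.02
    base_year: int = 2000

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        counts = (self.n_founders, self.n_generations, self.n_matings_per_generation,
                  self.litter_max, self.n_autosomes, self.snps_per_autosome,
                  self.chrom_length_bp)
        if min(counts) <= 0 or self.litter_mean <= 0:
            raise ValueError("all counts must be positive")
        for frac in (self.monomorphic_fraction, self.missing_rate):
            if not 0.0 <= frac < 1.0:
                raise ValueError("fractions must lie in [0, 1)")
        if self.mating_policy not in (RANDOM, AVOID_CLOSE, FULL_SIB_BURST):
            raise ValueError(f"unknown mating policy {self.mating_policy!r}")

    def chrom_lengths_morgans(self) -> np.ndarray:
        v = np.asarray(self.chrom_length_morgans, dtype=float)
        if v.ndim == 0:
            v = np.full(self.n_autosomes, float(v))
        if v.shape != (self.n_autosomes,):
            raise ValueError("chrom_length_morgans must be scalar or one value per autosome")
        return v


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------

def simulate_pedigree(cfg: SimConfig) -> PedigreeTable:
    """Simulate a pedigree under the configured mating policy.

    Founders form generation 0 and stay available as parents throughout
    (prolonged reproductive careers).  Each generation mates up to
    n_matings_per_generation pairs; litter sizes are 1 + Poisson(mean - 1)
    clipped at litter_max.  The avoid_close_relatives policy rejects
    pairs with pedigree kinship >= 0.125, falling back (with a warning)
    to the least-related pair when none is eligible; full_sib_burst
    forces full-sib matings in the first generation where full sibs of
    opposite sex exist, then switches to avoid_close_relatives.
    """
    rng = np.random.default_rng(cfg.seed)
    n_max = cfg.n_founders + cfg.n_generations * cfg.n_matings_per_generation * cfg.litter_max
    K = np.zeros((n_max, n_max))
    sire_i = np.full(n_max, -1, dtype=np.int64)
    dam_i = np.full(n_max, -1, dtype=np.int64)
    sex = np.empty(n_max, dtype="U1")
    gen_of = np.zeros(n_max, dtype=np.int64)
    n = 0

    def add(s, d, sx, g):
        nonlocal n
        i = n
        sire_i[i], dam_i[i], sex[i], gen_of[i] = s, d, sx, g
        row = np.zeros(i)
        if s >= 0:
            row += K[s, :i]
        if d >= 0:
            row += K[d, :i]
        row *= 0.5
        K[i, :i] = row
        K[:i, i] = row
        K[i, i] = 0.5 * (1.0 + (K[s, d] if (s >= 0 and d >= 0) else 0.0))
        n += 1
        return i

    for k in range(cfg.n_founders):
        add(-1, -1, "M" if k % 2 == 0 else "F", 0)

    burst_done = False
    litter_records = []  # (offspring_index, family_label, litter_label)
    for g in range(1, cfg.n_generations + 1):
        # parents recruit from the two most recent generations (short
        # generation interval); widen to the whole pool if a sex is absent
        recent = lambda i: max(0, g - 2) <= gen_of[i] < g
        males = [i for i in range(n) if sex[i] == "M" and recent(i)]
        females = [i for i in range(n) if sex[i] == "F" and recent(i)]
        if not males:
            males = [i for i in range(n) if sex[i] == "M" and gen_of[i] < g]
        if not females:
            females = [i for i in range(n) if sex[i] == "F" and gen_of[i] < g]
        policy = cfg.mating_policy
        if policy == FULL_SIB_BURST:
            sib_pairs = [(m, f) for m in males for f in females
                         if sire_i[m] >= 0 and sire_i[m] == sire_i[f]
                         and dam_i[m] == dam_i[f]]
            if sib_pairs and not burst_done:
                pairs = [sib_pairs[k] for k in
                         rng.choice(len(sib_pairs),
                                    size=min(cfg.n_matings_per_generation, len(sib_pairs)),
                                    replace=False)]
                burst_done = True
            else:
                policy = RANDOM if not burst_done else AVOID_CLOSE
        if policy == RANDOM:
            pairs = [(males[rng.integers(len(males))], females[rng.integers(len(females))])
                     for _ in range(cfg.n_matings_per_generation)]
        elif policy == AVOID_CLOSE:
            pairs = []
            dams_order = list(rng.permutation(females))[:cfg.n_matings_per_generation]
            for f in dams_order:
                eligible = [m for m in males if K[m, f] < CLOSE_KINSHIP]
                if eligible:
                    pairs.append((eligible[rng.integers(len(eligible))], f))
                else:
                    least = min(males, key=lambda m: K[m, f])
                    warnings.warn("no mate below the kinship threshold; "
                                  "falling back to the least-related pair")
                    pairs.append((least, f))
        # litters
        offspring_gen = []
        for s, d in pairs:
            size = int(min(cfg.litter_max, 1 + rng.poisson(max(cfg.litter_mean - 1, 0.0))))
            fam = f"FAM_{s}_{d}"
            lit = f"LIT_{s}_{d}_Y{g}"
            for _ in range(size):
                sx = "M" if rng.random() < 0.5 else "F"
                i = add(s, d, sx, g)
                offspring_gen.append(i)
                litter_records.append((i, fam, lit))
        if offspring_gen and len({sex[i] for i in offspring_gen}) == 1:
            flip = offspring_gen[rng.integers(len(offspring_gen))]
            sex[flip] = "F" if sex[flip] == "M" else "M"

    fam_of = {i: f for i, f, _ in litter_records}
    lit_of = {i: l for i, _, l in litter_records}
    width = len(str(n))
    ids = [f"IND{str(i + 1).zfill(width)}" for i in range(n)]
    df = pd.DataFrame({
        "id": ids,
        "sire": [ids[sire_i[i]] if sire_i[i] >= 0 else "0" for i in range(n)],
        "dam": [ids[dam_i[i]] if dam_i[i] >= 0 else "0" for i in range(n)],
        "birth_year": [cfg.base_year + int(gen_of[i]) for i in range(n)],
        "sex": [sex[i] for i in range(n)],
        "family_id": [fam_of.get(i, "") for i in range(n)],
        "litter_id": [lit_of.get(i, "") for i in range(n)],
        "genotyped": True,
        "is_bp": [gen_of[i] == 0 for i in range(n)],
    })
    return PedigreeTable(df)


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def _marker_map(cfg: SimConfig, rng) -> MarkerMap:
    frames = []
    for c in range(1, cfg.n_autosomes + 1):
        pos = np.array([], dtype=np.int64)
        while pos.size < cfg.snps_per_autosome:
            draw = rng.integers(1, cfg.chrom_length_bp + 1,
                                size=int(cfg.snps_per_autosome * 1.1) + 16)
            pos = np.unique(np.concatenate([pos, draw]))
        pos = np.sort(rng.choice(pos, size=cfg.snps_per_autosome, replace=False))
        frames.append(pd.DataFrame({
            "name": [f"SNP{c}_{k + 1}" for k in range(cfg.snps_per_autosome)],
            "chrom": str(c), "pos_bp": pos}))
    return MarkerMap(pd.concat(frames, ignore_index=True))


def drop_genes(ped: PedigreeTable, cfg: SimConfig,
               rng: np.random.Generator | None = None):
    """Drop labelled founder alleles down the pedigree.

    Returns (GenotypeMatrix, MarkerMap, truth) where truth is a DataFrame
    (index id) of realized IBD fractions, genome-wide and per autosome,
    computed from founder-allele labels (two identical labels = IBD).
    Each founder carries two unique labels, so founder realized IBD is 0.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    marker_map = _marker_map(cfg, rng)
    n_snps = len(marker_map)
    n = len(ped)
    founders = [ped.index_of(i) for i in ped.founders()]
    lengths_m = cfg.chrom_lengths_morgans()

    # founder allele frequencies and the monomorphic fraction
    a, b = cfg.founder_maf_beta
    p = rng.beta(a, b, size=n_snps)
    mono = rng.random(n_snps) < cfg.monomorphic_fraction
    p[mono] = np.where(rng.random(mono.sum()) < 0.5, 0.0, 1.0)

    n_hap = 2 * len(founders)
    alleles = (rng.random((n_hap, n_snps)) < p).astype(np.int8)  # 1 = reference

    # per-chromosome SNP genetic positions and slices
    chrom_slices = [marker_map.chrom_slice(c) for c in marker_map.chroms]
    pos = marker_map.df["pos_bp"].to_numpy()
    gpos = [pos[sl] / cfg.chrom_length_bp * lengths_m[k]
            for k, sl in enumerate(chrom_slices)]

    def gamete(pat: np.ndarray, mat: np.ndarray) -> np.ndarray:
        out = np.empty(n_snps, dtype=np.int16)
        for k, sl in enumerate(chrom_slices):
            n_x = rng.poisson(lengths_m[k])
            cross = np.sort(rng.random(n_x) * lengths_m[k])
            phase = (np.searchsorted(cross, gpos[k]) + rng.integers(2)) % 2
            out[sl] = np.where(phase == 0, pat[sl], mat[sl])
        return out

    hap_p = np.empty((n, n_snps), dtype=np.int16)
    hap_m = np.empty((n, n_snps), dtype=np.int16)
    founder_rank = {idx: r for r, idx in enumerate(founders)}
    for i in ped.topo:
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if s < 0 and d < 0:
            r = founder_rank[i]
            hap_p[i] = 2 * r
            hap_m[i] = 2 * r + 1
            continue
        if s < 0 or d < 0:
            raise ValueError("gene dropping requires both parents known or none")
        hap_p[i] = gamete(hap_p[s], hap_m[s])
        hap_m[i] = gamete(hap_p[d], hap_m[d])

    ibd = hap_p == hap_m
    truth = pd.DataFrame(index=pd.Index(ped.ids, name="id"))
    truth["genome"] = ibd.mean(axis=1)
    for k, c in enumerate(marker_map.chroms):
        truth[str(c)] = ibd[:, chrom_slices[k]].mean(axis=1)

    cols = np.arange(n_snps)
    geno = (alleles[hap_p, cols] + alleles[hap_m, cols]).astype(np.int8)
    if cfg.missing_rate > 0:
        geno[rng.random(geno.shape) < cfg.missing_rate] = MISSING

    mm = marker_map.df.copy()
    mm["is_monomorphic_bp"] = mono
    return GenotypeMatrix(ped.ids, geno), MarkerMap(mm), truth


def simulate_dataset(cfg: SimConfig):
    """Pedigree + genotypes + truth in one call (one seed)."""
    ped = simulate_pedigree(cfg)
    geno, marker_map, truth = drop_genes(ped, cfg)
    return ped, geno, marker_map, truth
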