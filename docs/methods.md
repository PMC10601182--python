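# Methods

This note records the models, numerical conventions and design choices
behind `autozyg`, in enough detail to reproduce or audit any stage.

## Genealogical statistics

The pedigree is a directed acyclic parent map; founders are individuals
with both parents unknown, and an individual with one known parent
contributes only that side to its depth. Inbreeding coefficients are
computed with the Meuwissen & Luo ancestor-tracing algorithm:
`A_ii = Σ_j L_ij² D_j` over ancestors `j`, with
`D_j = 0.5 − 0.25(F_sire(j) + F_dam(j))` and the `F` of an unknown
parent taken as −1, visiting ancestors youngest-first so each
contributes one coalesced path coefficient. The full coancestry matrix
uses the tabular method (`f_ij = (f_sj + f_dj)/2` for `j` older than
`i`, `f_ii = (1 + f_sd)/2`), built row-wise in topological order. The
two routes agree with the classical recursive kinship recursion to
1e-12; the test suite enforces this on random pedigrees of up to 50
individuals, including selfing and tangled multi-path ancestries.

Equivalent discrete generations follow the recursion
`t_i = Σ_{known parents p} (1 + t_p)/2`, and fully traced generations
`G_i = 1 + min(G_sire, G_dam)` with `G = 0` when any parent is unknown.

`ΔF_i = 1 − (1−F)^(1/(t−1))` is left undefined for `t ≤ 1` (the exponent
is singular at `t = 1`, and an untraced pedigree carries no rate
information); undefined values are excluded from cohort means, never
zero-filled — zero-filling would bias Ne upward deterministically.
`Ne_Cij` averages `ΔC_ij` over **all** unordered within-cohort pairs
(no sampling), excluding self-pairs. A cohort whose mean increase is
non-positive reports `Ne = +inf` (no measurable loss), and a cohort with
no defined increments reports NaN; both propagate explicitly rather
than silently.

Reference subpopulations are built by birth year (with a configurable
merge map for sparse years, e.g. absorbing 2010-born animals into the
2009 cohort), by complete generation count, or as the subset with
`t ≥ 2` (default threshold).

## Run detection

`detect_runs` emits every **maximal conforming window**: endpoints must
be SNPs of the run's own state (homozygous for ROH, heterozygous for
HRR — a run may not start or end on an opposite-state or missing SNP),
interruption counts within the window must respect `max_opposite` and
`max_missing`, and no gap between consecutive mapped SNPs may exceed
`max_gap_bp`. A gap larger than the cap *closes* the run rather than
merely splitting candidates — the stricter of the two readings of the
gap rule, chosen because a 1-Mb unmapped hole gives no evidence of
continued homozygosity. Two maximal windows may overlap when an
interruption budget forces a trade-off between extending left or right;
all are emitted, then filtered by `min_snps` and `min_length_bp`.
Coordinates are 1-based inclusive; run length is
`end_bp − start_bp + 1` with boundaries at the first/last SNP of the
run (not extended to midpoints), making `Σ L` reproducible bit-exactly.
The implementation is a two-pointer sweep with prefix-sum interruption
counts; the suite checks it against an exhaustive window-enumeration
oracle on 1,000 random vectors for both parameter sets.

Defaults mirror standard array-density choices: ROH
`min_snps=20, max_opposite=5, max_missing=5, min_length=1 kb,
max_gap=1 Mb`; HRR `10/5/5/1 kb/1 Mb` (HRR are short — mostly < 100 kb —
so the SNP minimum is halved and "opposite" means homozygous).

Monomorphic SNPs participate in run detection (they are genuine
homozygous calls on the array) but are excluded from the
frequency-based estimators, whose denominators `2p(1−p)` are singular
at `p ∈ {0, 1}`. Population-level ROH/HRR regions are the union-merge of
per-individual segments with a distinct-contributor count, exported as
0-based half-open BED.

The Mendelian filter removes a SNP entirely when **any**
parents-offspring trio shows an impossible transmission (e.g. parents
0/0 with offspring carrying a reference allele); cells with a missing
genotype contribute no evidence. This is deliberately the only genotype
filter: MAF or call-rate pruning removes rare alleles and manufactures
apparent inbreeding from identity-by-state.

## Estimators, adjustment, jackknife

`L_AUTO` is the marker-map span (per autosome: last − first SNP bp + 1),
not an external assembly length, so `F_ROH = 1` is attainable and the
statistic is self-contained in the data; an override with assembly
lengths is available. `F_ROH` sums the *covered* length (union of
segments), keeping it in [0, 1] even when maximal windows overlap.

`F_LH` and `F_YAN` use base-population reference-allele frequencies
obtained by allele counting over BP members, excluding missing calls
SNP-wise. Missing genotypes are removed from both `S` and `F_NEJ`. By
default `F_NEJ` is computed over the polymorphic-in-BP loci only, the
same set entering the correction sums (a mode including monomorphic
loci exists). Both estimators are invariant to which allele is labelled
"reference" provided `x` and `p` flip together; the PED importer makes
that labelling deterministic (lexicographically smaller allele) and
logs it per SNP.

BP adjustment `(F − F_BP)/(1 − F_BP)` is applied genome-wide and, for
the jackknife path, per autosome with each autosome's own BP mean (the
partitioning of diversity across chromosomes is itself of interest).
Negative adjusted values are retained, never truncated — their
frequency is informative. The jackknife over autosomes is the
bias-corrected pseudo-value (Quenouille/Tukey) form — the cited
procedure in the source literature is not spelled out, so the standard
form is implemented and labelled as such. Unweighted by default, in
which case pseudo-values reduce to the per-autosome values and the
estimate to their plain mean; SNP-count or length weights are a flag.
Undefined autosome values (e.g. a chromosome whose BP mean is 1) are
dropped with a warning and `n` reduced.

## Increments and Ne

`ΔtF = 1 − (1−F)^(1/t)` deliberately uses exponent `1/t`, not
`1/(t−1)`: the genomic zero point is the base population itself, not
the parents' generation. Hence `ΔtF < ΔF` for the same `F` and `t` — the
genomic-style per-generation rate is the smaller. Negative adjusted
values pass through both increment formulas. `ΔpF` requires both
parental values; individuals with non-genotyped parents are excluded
from cohort means and reported as such. RMSE compares each genomic Ne
series over the reference cohorts against both genealogical references
(`Ne_Fi` and `Ne_Cij`), for each adjustment basis, and refuses to
average over undefined members — an infinite cohort Ne makes that RMSE
unavailable rather than silently shrinking `n`.

## The simulator

`simulate_pedigree` emulates a small conserved herd: 6 founders by
default, up to 4 generations, parents recruited from the two most
recent generations (short generation interval), litters of
`1 + Poisson(mean − 1)` capped at 34, and three mating policies —
`random`, `avoid_close_relatives` (rejects pairs with pedigree kinship
≥ 0.125, i.e. half-sib-or-closer; falls back to the least-related pair
with a warning when no eligible pair exists), and `full_sib_burst`
(full-sib matings in the first generation where full sibs of opposite
sex exist, then the avoidance policy — the documented early
mismanagement-then-strict-policy history of such programmes).

`drop_genes` assigns every founder two uniquely labelled haplotypes and
transmits them with Haldane recombination: crossover count Poisson in
the chromosome's genetic length, uniform placement, no interference
(the map function is a single well-isolated routine and thus
pluggable). Founder allele frequencies are Beta(0.8, 0.8) — a U-shaped,
array-like site-frequency spectrum — with a configured fraction of
sites forced monomorphic (default 0.30, matching the roughly 30%
monomorphic content of the emulated array) and genotypes masked at the
missing rate (default 0.02, inside a 0.97 call-rate floor). Realized
IBD is read off the labels exactly, per SNP, giving each individual a
truth value the estimators must recover. Defaults use 18 autosomes of
100 Mb / 1 Morgan and 2,000 SNPs per autosome — a deliberately
scaled-down array density (36k genome-wide) that keeps the full
pipeline runnable in tens of seconds while remaining dense enough for
run detection to resolve IBD segments.

What the generator does **not** emulate: genotyping error and allelic
dropout (so the Mendelian filter removes nothing on simulated data —
its logic is tested on constructed trios), linkage disequilibrium
within founder haplotypes (founder alleles are drawn independently per
site), mutation, selection, sex chromosomes, and crossover
interference. Passing tests therefore demonstrate correctness of the
statistics given the transmission model, not robustness to array
artefacts.

A consequence worth knowing: at scaled-down density the raw coverage
estimators saturate (IBS runs abound; raw `F_ROH` near 1) — exactly the
behaviour that motivates BP adjustment — and under a strict
minimum-coancestry policy some simulated cohorts legitimately have zero
mean inbreeding increase, so their genealogical `Ne` is infinite and
the corresponding RMSE entries are unavailable. The acceptance script
reports every finite quantity and omits undefined ones rather than
imputing.

## Problem sizes and tolerances

The default test run simulates populations of tens-to-hundreds of
individuals with 3–6 autosomes; the acceptance script uses the full
study conditions (6 founders, 4 generations, 18 autosomes × 2,000
SNPs, ~300 individuals) plus a recovery experiment of 500 full-sib
offspring at 18 × 600 polymorphic SNPs, where mean realized IBD and
mean raw `F_LH` must equal 0.25 within 3 family-level standard errors
and BP-adjusted means must track the truth (0.02 absolute for the
frequency-based estimators, 0.1 for the density-limited coverage-based
ones). Exact identities (kinship oracles, jackknife pseudo-values,
closed-form increments) are asserted at 1e-9 to 1e-12.
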