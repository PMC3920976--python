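# Methods

Statistical definitions, simulator model and the numerical conventions
used by `sweepscan`. All statistics operate on a `HaplotypePanel`: a
matrix of phased haplotypes (rows) by biallelic SNPs (columns) with
alleles coded 0 (ancestral when polarized), 1 (derived) and −1
(missing), base-pair positions, per-haplotype population labels and an
optional genetic map (fallback: a constant 1 cM/Mb, recorded in panel
metadata).

## Per-SNP statistics

### FST (Weir–Cockerham, haploid)

For two populations with sample sizes n₁, n₂ and derived-allele
frequencies p̃₁, p̃₂ at a SNP, we compute the Weir & Cockerham (1984)
variance components for haploid samples:

- n̄ = (n₁+n₂)/2, n_c = (n₁+n₂ − (n₁²+n₂²)/(n₁+n₂)),
- p̄ = (n₁p̃₁+n₂p̃₂)/(n₁+n₂), s² = Σ nᵢ(p̃ᵢ−p̄)²/n̄ (sum over the 2 pops),
- a = (n̄/n_c)·(s² − (p̄(1−p̄) − s²/2)/(2n̄−1)),
- b = (2n̄/(2n̄−1))·(p̄(1−p̄) − s²/2),
- FST = a/(a+b).

Haploid data have no within-individual heterozygosity term. SNPs
monomorphic across both samples, or with fewer than two non-missing
haplotypes in either population, are undefined (NaN). Missing calls are
dropped per population per SNP (complete-case frequencies). Estimates
can be slightly negative at undifferentiated SNPs; they are reported
as-is (truncation would bias window proportions).

### Tajima's D

For a window with n haplotypes, S segregating sites and mean pairwise
difference π (per-site terms 2d(n−d)/(n(n−1)) summed over sites, with
d the derived count), D = (π − S/a₁)/√(e₁S + e₂S(S−1)) using the
standard constants a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ (Tajima 1989).
Windows are 51-SNP (25 SNPs per side, truncated at chromosome ends) to
match the windowing used everywhere else; bp-interval windows are
half-open [start, end). At least 4 haplotypes and S ≥ 1 are required;
otherwise the window is undefined.

### EHH, iHS

EHH at distance x from a core SNP, for a carrier class (derived,
ancestral or pooled), is the probability that two randomly chosen
carrier haplotypes are identical at every SNP between the core and x.
Computation walks SNP-by-SNP outward, refining a partition of the
carriers; haplotypes with a missing call at the next SNP are dropped
from that point outward. The curve is truncated where EHH < 0.05 and
capped at 2.5 cM per side; a curve is undefined with fewer than two
carriers.

iHH is the trapezoidal integral of EHH over genetic distance (cM),
summed over both directions. Raw iHS = ln(iHH_ancestral/iHH_derived);
unpolarized SNPs and SNPs with derived frequency outside [0.05, 0.95]
are excluded. Raw scores are standardized to mean 0 / SD 1 (ddof = 0)
within 20 equal derived-frequency bins (left-closed, last bin includes
1.0); bins with fewer than two scores stay undefined. Negative iHS
means unusually long derived haplotypes.

### XP-EHH

For populations A and B, EHH is computed on the pooled carriers (all
haplotypes) of each population separately, with a shared truncation
point: both curves stop one step after the first SNP where both have
EHH < 0.05 (and at the shared maximum extension). Raw XP-EHH =
ln(iHH_A/iHH_B); scores are z-normalized over the scan. Positive
values mean longer haplotypes in A.

## Empirical ranking

- **Window proportions**: for each SNP, the fraction of SNPs in its
  51-SNP window exceeding a threshold (|iHS| > 2, or FST above the
  top-5% cutoff), with undefined SNPs excluded from numerator and
  denominator; windows truncate at the ends.
- **Top cutoff**: top fraction p of N values is `sorted_desc[floor(p·N)]`
  (requires ≥ 20 defined values); a SNP is "top 1%" when its value is
  strictly above the p = 0.01 cutoff.
- **−log10(Q)**: a value's rank fraction, −log10(rank/N) over defined
  values, with ties taking the maximal (least extreme) rank. 3.0 means
  the most extreme ~0.1%. Tajima's D ranks low-tail; everything else
  ranks high-tail.
- **Gene empirical P**: (1 + #matched windows ≥ observed)/(1 + #matched),
  over windows whose SNP count is within ±20% of the gene's; undefined
  with fewer than 100 matched windows.

## Region evidence

A region query collects, over a half-open 1 Mb interval centered on
the region (center given in Mb), the per-statistic maxima of the
−log10(Q) and −log10(P) columns, any top-1% FST SNPs, and the minimum
gene empirical P. Classification:

- `HAPMAP_STYLE`: qualifies if any windowed −log10(Q) (iHS, D, FST)
  ≥ 3.0 (`WINDOW_SCORE`), a top-1% FST SNP is present (`TOP1PCT_FST`),
  or gene empirical P < 0.01 (`GENE_EMPIRICAL_P`).
- `HGDP_STYLE`: qualifies if any of the −log10(P) scores for FST, iHS
  or XP-EHH is ≥ 3.0 (`WINDOW_SCORE`).

The ≥ 3.0 threshold is inclusive: scores are reported rounded to one
decimal, and a printed 3.0 counts as reaching the threshold.
Concordance between two classified lists is the set of regions
qualifying in both, matched on canonical region names (uppercased,
order-insensitive comma-separated gene sets).

## Forward Wright–Fisher simulator

Haploid forward-in-time model:

- **Reproduction**: each of N children picks two parents uniformly (or
  with selection weights 1 + s on focal-allele carriers) and inherits a
  mosaic with Poisson(rec·L) crossovers at uniform bp positions.
- **Mutation**: Poisson(μ·L·N) new mutations per generation, each at a
  previously unused bp (infinite sites on an integer grid, tracked in a
  global used-position registry).
- **Burn-in**: 6N generations from a monomorphic start (several
  haploid coalescent timescales of N generations).
- **Sweep conditioning**: the focal mutation starts as `init_copies`
  copies at a uniform position in the middle half of the locus; the
  run restarts from the pre-sweep snapshot whenever the allele is lost
  or overshoots the sampling band (target frequency ± band), failing
  loudly after `max_restarts`. This conditioning samples successful
  trajectories, which are faster than unconditioned ones — a known and
  intended bias shared with standard sweep simulators.
- **Splits**: the population is copied into n_pops demes which evolve
  independently for `split_time` generations. Post-split matrices are
  not pruned per deme: a variant fixed or lost in one deme may still
  segregate between demes, and that between-population difference is
  the FST signal.
- **Sampling**: `sample_size` haplotypes per deme without replacement;
  only sites polymorphic in the sample are kept (the focal site is
  always kept); the genetic map is positions · rec · 100 cM.

The generator emulates neutral drift, partial hard sweeps and simple
divergence. It does not model diploidy, dominance, migration,
population growth, gene conversion or variable recombination maps.

The synthetic statistic-table generator plants chosen score values at
given intervals on top of configurable noise laws (uniform or
exponential per column), rejecting overlapping plants and plants whose
interval contains no SNP.

## Numerical and testing conventions

- EHH stepping is compiled with numba (chunked prefix-grouping over
  128-SNP blocks) with a pure-Python fallback for panels containing
  missing data; both paths are tested for exact agreement against an
  all-pairs enumeration oracle.
- Trapezoidal integration uses `numpy.trapezoid`; quadrature agrees
  with a hand-written oracle to 1e-15 and with fine-grid quadrature to
  1e-9 on piecewise-linear curves.
- All TSV output writes `NA` for missing values with fixed column
  order; re-reading is lossless and identical seeds produce
  byte-identical VCFs and reports.
- The acceptance suite validates: the two packaged-table counts
  (19 and 16 qualifying regions), oracle equivalence (EHH exact, FST
  to 1e-12, ranks exact), neutral distributional behavior (mean D,
  standardization by construction, |iHS| > 2 tail fraction), sweep
  signal recovery (focal iHS standardized against matched neutral
  background is negative in ≥ 80% of 50 replicates at s = 0.05, target
  frequency 0.7, in a recombination-dominated regime with μ = rec),
  planted-signal recovery in 100/100 synthetic tables, and
  byte-determinism.
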