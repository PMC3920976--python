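# sweepscan

Selection-scan statistics and candidate-region evidence classification
for phased haplotype panels, plus a forward Wright–Fisher simulator for
generating test data with known, planted signals.

## What it does

Recent positive selection leaves characteristic footprints in
population genetic data: unusually long haplotypes around the selected
allele, a skewed site-frequency spectrum, and large allele-frequency
differences between populations. `sweepscan` computes the standard
statistics that detect these footprints and turns them into per-region
evidence calls:

- **FST** per SNP (Weir–Cockerham variance-component estimator for
  haploid samples) — population differentiation.
- **Tajima's D** in 51-SNP windows — site-frequency-spectrum skew.
- **EHH / iHS** — extended haplotype homozygosity decay and the
  integrated haplotype score, standardized in 20 derived-allele
  frequency bins; detects partial sweeps at moderate frequency.
- **XP-EHH** — cross-population haplotype-length contrast; detects
  sweeps near fixation in one population.
- **Empirical ranking** — window proportions (fraction of |iHS| > 2
  SNPs, fraction of top-5% FST SNPs in a 51-SNP window), genome-wide
  empirical rank scores −log10(Q) = −log10(rank/N), top-1% FST flags,
  and gene-level empirical P values against SNP-count-matched windows.
- **Region evidence** — 1 Mb candidate-interval queries over the
  per-SNP table, classified under two rule families:
  `HAPMAP_STYLE` (any windowed −log10(Q) ≥ 3.0, a top-1% FST SNP, or
  gene empirical P < 0.01) and `HGDP_STYLE` (any of the FST / iHS /
  XP-EHH −log10(P) scores ≥ 3.0), plus cross-dataset concordance.
- **Simulation** — a forward Wright–Fisher haploid simulator
  (recombination, infinite-sites mutation, viability selection,
  population splits, restart-conditioned partial sweeps) and a
  synthetic statistic-table generator with planted signals.

## Worked example (CLI)

Simulate a two-population panel, scan it, and query a candidate region:

```sh
$ sweepscan simulate --seed 11 --n-haploid 200 --length-bp 500000 \
    --n-pops 2 --split-time 120 --sample-size 100 --out panel.vcf
wrote 188 variants to panel.vcf

$ sweepscan scan --vcf panel.vcf --pop-map pops.tsv --out stats.tsv
wrote 188 SNP rows to stats.tsv

$ printf 'name\tchrom\tpos_mb\nCENTER\t1\t0.25\n' > regions.tsv
$ sweepscan regions --stats stats.tsv --regions regions.tsv \
    --width-bp 250000 --out-dir reports
0/1 regions qualify under HAPMAP_STYLE
```

`pops.tsv` maps each diploid sample to a population
(`S0000<TAB>POP1` …). The statistic table `stats.tsv` has one row per
SNP with columns such as `freq_POP1`, `tajd_POP1`,
`neglogq_tajd_POP1`, `ihs_std_POP1`, `wprop_ihs_POP1`,
`fst_POP1_POP2`, `fst_top1_POP1_POP2` and `xpehh_POP1_POP2`.

## Worked example (library)

```python
from sweepscan import (EvidenceRuleSet, classify_all, concordance,
                       load_hapmap_evidence, load_hgdp_evidence)

hapmap = classify_all(load_hapmap_evidence(),
                      EvidenceRuleSet(family="HAPMAP_STYLE"))
hgdp = classify_all(load_hgdp_evidence(),
                    EvidenceRuleSet(family="HGDP_STYLE"))
print(sum(e.qualifies for e in hapmap))   # 19
print(sum(e.qualifies for e in hgdp))     # 16
print(len(concordance(hapmap, hgdp)))     # 8
```

The packaged data (`sweepscan/data/`) are a 74-region candidate list
for systemic lupus erythematosus (SLE) susceptibility loci and the two
per-region evidence tables derived from published genome-wide scans of
the HapMap and HGDP panels.

## Input formats

- **VCF** (v4.x): phased GT (`|` separator), biallelic records only; an
  `AA=` INFO tag marks the ancestral allele (records with AA equal to
  ALT are flipped so that allele 1 always means derived). Unphased,
  multiallelic and duplicate-position records are skipped with logged
  counts.
- **Haplotype TSV** (compact fixture format): a header line
  `#positions<TAB>p1<TAB>p2…`, then one row per haplotype:
  `pop<TAB>hapID<TAB>0/1 string` with `.` for a missing call.
- **Region list TSV**: columns `name`, `chrom`, `pos_mb` (interval
  centers in megabases; multi-gene regions comma-join the gene names).
- **Run config YAML**: keys mirror the CLI flags; see
  `sweepscan.config.RunConfig`.

See `docs/methods.md` for the statistical definitions, simulator model
and numerical conventions.
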