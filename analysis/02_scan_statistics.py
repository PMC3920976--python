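#!/usr/bin/env python
"""Run the full per-SNP statistic scan on the simulated two-population
panel from step 01.

Writes results/scan/snp_stats.tsv with derived frequencies, Tajima's D,
standardized iHS, per-SNP FST (plus top-1% flags), XP-EHH and the
empirical -log10 rank scores of each ranked statistic.
"""

from pathlib import Path

from sweepscan.io import read_vcf
from sweepscan.scan import scan_panel

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    vcf = ROOT / "panels" / "two_pop.vcf"
    pops = ROOT / "panels" / "two_pop.pops.tsv"
    if not vcf.exists():
        raise SystemExit("run analysis/01_simulate_panels.py first")
    pop_map = dict(line.split() for line in pops.read_text().splitlines())
    panel = read_vcf(vcf, pop_map)
    table = scan_panel(panel)
    out = ROOT / "scan"
    out.mkdir(parents=True, exist_ok=True)
    table.to_tsv(out / "snp_stats.tsv")
    print(f"wrote {len(table)} SNP rows, {len(table.df.columns)} columns "
          f"-> {out / 'snp_stats.tsv'}")


if __name__ == "__main__":
    main()
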