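#!/usr/bin/env python
"""Query candidate intervals on the step-02 scan output and classify
their evidence under the HAPMAP_STYLE rule.

Uses three synthetic candidate regions spanning the simulated locus and
writes results/regions/evidence_scan.tsv.
"""

from pathlib import Path

from sweepscan.evidence import EvidenceRuleSet, classify_all, query_region
from sweepscan.io import write_reports
from sweepscan.panel import RegionSpec
from sweepscan.stats_table import SnpStatTable

ROOT = Path(__file__).resolve().parent.parent / "results"

REGIONS = [
    RegionSpec("LEFT", "1", 0.125),
    RegionSpec("CENTER", "1", 0.250),
    RegionSpec("RIGHT", "1", 0.375),
]


def main() -> None:
    stats = ROOT / "scan" / "snp_stats.tsv"
    if not stats.exists():
        raise SystemExit("run analysis/02_scan_statistics.py first")
    table = SnpStatTable.from_tsv(stats)
    rules = EvidenceRuleSet(family="HAPMAP_STYLE")
    evidence = classify_all(
        [query_region(table, r, width_bp=250_000) for r in REGIONS], rules)
    out = ROOT / "regions"
    write_reports({"scan": evidence}, None, out)
    for ev in evidence:
        print(f"{ev.region.name}: {ev.n_snps} SNPs, qualifies={ev.qualifies}"
              f" reasons={ev.reasons}")


if __name__ == "__main__":
    main()
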