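#!/usr/bin/env python
"""Classify the packaged per-region evidence tables and compute their
cross-dataset concordance.

Writes results/tables/: evidence_hapmap.tsv, evidence_hgdp.tsv and
concordance.tsv (regions qualifying in both datasets).
"""

from pathlib import Path

from sweepscan.evidence import EvidenceRuleSet, classify_all, concordance
from sweepscan.io import (load_hapmap_evidence, load_hgdp_evidence,
                          write_reports)

OUT = Path(__file__).resolve().parent.parent / "results" / "tables"


def main() -> None:
    hapmap = classify_all(load_hapmap_evidence(),
                          EvidenceRuleSet(family="HAPMAP_STYLE"))
    hgdp = classify_all(load_hgdp_evidence(),
                        EvidenceRuleSet(family="HGDP_STYLE"))
    conc = concordance(hapmap, hgdp)
    write_reports({"hapmap": hapmap, "hgdp": hgdp}, conc, OUT)
    print(f"HAPMAP_STYLE qualifying: {sum(e.qualifies for e in hapmap)}"
          f" of {len(hapmap)}")
    print(f"HGDP_STYLE qualifying:   {sum(e.qualifies for e in hgdp)}"
          f" of {len(hgdp)}")
    print(f"concordant regions:      {len(conc)}")
    for name in conc["region"]:
        print(f"  {name}")


if __name__ == "__main__":
    main()
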