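"""Candidate-region evidence: 1 Mb interval queries, the two evidence
rule families, and cross-dataset concordance.

The headline procedure of this package: around each candidate region a
1 Mb interval is queried from a per-SNP statistic table; the maximum
empirical -log score per statistic, any top-1% FST SNPs, and the minimum
gene-level empirical P are extracted; and a region counts as showing
evidence for recent positive selection if it meets at least one
criterion of the chosen rule family.

Two families mirror the two public genome-scan browsers the statistics
come from:

* ``HAPMAP_STYLE`` — any windowed -log10(Q) >= 3.0 for iHS, Tajima's D
  or FST, OR a SNP in the pair-wise top 1% of FST inside the interval,
  OR a gene empirical P < 0.01.
* ``HGDP_STYLE`` — any -log10 empirical P >= 3.0 for FST, iHS or XP-EHH.

Threshold comparisons are inclusive (>= 3.0): published evidence tables
of this design contain qualifying rows whose printed maximum is exactly
3.0, so the inclusive reading is the one consistent with practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import RegionSpec
from .stats_table import SnpStatTable

logger = logging.getLogger(__name__)

REASON_WINDOW = "WINDOW_SCORE"
REASON_TOP1 = "TOP1PCT_FST"
REASON_GENE_P = "GENE_EMPIRICAL_P"

HAPMAP_WINDOW_STATS = ("ihs", "tajd", "fst")
HGDP_WINDOW_STATS = ("fst", "ihs", "xpehh")


@dataclass
class EvidenceRuleSet:
    family: str = "HAPMAP_STYLE"          # or "HGDP_STYLE"
    window_score_threshold: float = 3.0   # inclusive
    gene_p_threshold: float = 0.01        # exclusive (<)

    def __post_init__(self) -> None:
        if self.family not in ("HAPMAP_STYLE", "HGDP_STYLE"):
            raise ValueError(f"unknown rule family {self.family!r}")
        if self.window_score_threshold <= 0 or self.gene_p_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class RegionEvidence:
    """Per-region maxima, flags and the evidence-rule outcome."""

    region: RegionSpec
    max_neglogq: dict = field(default_factory=dict)  # stat -> (value, label)
    max_neglogp: dict = field(default_factory=dict)
    top1pct_fst_hits: list = field(default_factory=list)  # (rsid, fst, pair)
    min_gene_p: tuple | None = None                  # (value, pop)
    n_snps: int = 0
    qualifies: bool = False
    reasons: list = field(default_factory=list)


def query_region(stats: SnpStatTable, region: RegionSpec,
                 width_bp: int = 1_000_000) -> RegionEvidence:
    """Extract maxima and top-1% FST flags in the interval around a region.

    The interval is half-open ``[center - width/2, center + width/2)``.
    For every -log score column the maximum defined value in the interval
    is recorded per statistic with its population label.  An interval
    with no SNPs gives empty evidence (and a warning).
    """
    half = width_bp // 2
    start = region.center_bp - half
    end = region.center_bp + half
    rows = stats.in_interval(region.chrom, start, end)
    ev = RegionEvidence(region=region, n_snps=len(rows))
    if rows.empty:
        logger.warning("no SNPs in %d bp interval around %s", width_bp, region.name)
        return ev
    for kind, store in (("q", ev.max_neglogq), ("p", ev.max_neglogp)):
        for (stat, label), col in stats.score_columns(kind).items():
            vals = rows[col].to_numpy(dtype=float)
            if not np.isfinite(vals).any():
                continue
            best = float(np.nanmax(vals))
            prev = store.get(stat)
            if prev is None or best > prev[0]:
                store[stat] = (best, label)
    for pair, col in stats.top1_flag_columns().items():
        hit = rows[rows[col].fillna(False).astype(bool)]
        fst_col = f"fst_{pair}"
        for _, r in hit.iterrows():
            val = float(r[fst_col]) if fst_col in rows.columns else float("nan")
            ev.top1pct_fst_hits.append((str(r["rsid"]), val, pair))
    return ev


def classify_region(ev: RegionEvidence,
                    rules: EvidenceRuleSet) -> RegionEvidence:
    """Fill ``qualifies`` and ``reasons`` according to one rule family."""
    reasons: list[str] = []
    thr = rules.window_score_threshold
    if rules.family == "HAPMAP_STYLE":
        if any(ev.max_neglogq.get(s, (-np.inf, ""))[0] >= thr
               for s in HAPMAP_WINDOW_STATS):
            reasons.append(REASON_WINDOW)
        if ev.top1pct_fst_hits:
            reasons.append(REASON_TOP1)
        if ev.min_gene_p is not None and ev.min_gene_p[0] < rules.gene_p_threshold:
            reasons.append(REASON_GENE_P)
    else:  # HGDP_STYLE
        if any(ev.max_neglogp.get(s, (-np.inf, ""))[0] >= thr
               for s in HGDP_WINDOW_STATS):
            reasons.append(REASON_WINDOW)
    ev.reasons = reasons
    ev.qualifies = bool(reasons)
    return ev


def classify_all(evidence: list[RegionEvidence],
                 rules: EvidenceRuleSet) -> list[RegionEvidence]:
    return [classify_region(ev, rules) for ev in evidence]


def concordance(list_a: list[RegionEvidence],
                list_b: list[RegionEvidence]) -> pd.DataFrame:
    """Regions qualifying in both evidence lists, with both sides' maxima.

    Region identity is the canonical region name (case-insensitive,
    gene-list order-insensitive).  Rows keep list A's order.
    """
    by_b = {ev.region.canonical_name(): ev for ev in list_b if ev.qualifies}
    rows = []
    for ev_a in list_a:
        if not ev_a.qualifies:
            continue
        ev_b = by_b.get(ev_a.region.canonical_name())
        if ev_b is None:
            continue
        row = {"region": ev_a.region.name,
               "chrom": ev_a.region.chrom,
               "center_mb": ev_a.region.center_mb}
        for side, ev in (("a", ev_a), ("b", ev_b)):
            for stat, (val, label) in sorted(ev.max_neglogq.items()):
                row[f"{side}_neglogq_{stat}"] = val
                row[f"{side}_neglogq_{stat}_pop"] = label
            for stat, (val, label) in sorted(ev.max_neglogp.items()):
                row[f"{side}_neglogp_{stat}"] = val
                row[f"{side}_neglogp_{stat}_pop"] = label
            if ev.top1pct_fst_hits:
                best = max(ev.top1pct_fst_hits,
                           key=lambda h: (np.nan_to_num(h[1], nan=-1.0)))
                row[f"{side}_top1_fst"] = best[1]
                row[f"{side}_top1_fst_pair"] = best[2]
            if ev.min_gene_p is not None:
                row[f"{side}_min_gene_p"] = ev.min_gene_p[0]
                row[f"{side}_min_gene_p_pop"] = ev.min_gene_p[1]
            row[f"{side}_reasons"] = ";".join(ev.reasons)
        rows.append(row)
    return pd.DataFrame(rows)
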