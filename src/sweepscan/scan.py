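"""End-to-end scan: panel in, per-SNP statistic table out.

Bundles the individual statistics into the browser-style table the
region stage consumes: per-population derived frequencies, pairwise
FST with top-5% window proportions and top-1% flags, 51-SNP-window
Tajima's D, standardized iHS with |iHS| > 2 window proportions, and
XP-EHH, plus the empirical -log rank scores of each ranked statistic.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np

from . import freq, haplo, ranking
from .panel import HaplotypePanel
from .stats_table import SnpStatTable

logger = logging.getLogger(__name__)


def scan_panel(panel: HaplotypePanel,
               config: ranking.RankConfig | None = None,
               statistics: tuple = ("fst", "tajd", "ihs", "xpehh"),
               ) -> SnpStatTable:
    """Compute the selected statistics and their empirical rank scores.

    HapMap-browser-style scores (``neglogq_*``) rank, per population or
    pair: the |iHS| > 2 window proportion, Tajima's D (low is extreme)
    and the FST top-5% window proportion.  HGDP-browser-style scores
    (``neglogp_*``) rank per-SNP FST, the iHS window proportion and
    normalized XP-EHH.  Statistics needing more data than the panel has
    (e.g. XP-EHH with one population) are skipped with a log line.
    """
    cfg = config or ranking.RankConfig()
    pops = panel.populations
    pairs = list(itertools.combinations(pops, 2))
    table = SnpStatTable.from_positions(panel.chrom, panel.positions)

    for pop in pops:
        table.add(f"freq_{pop}", freq.derived_frequency(panel, pop))

    if "tajd" in statistics:
        for pop in pops:
            d = freq.tajimas_d_snp_windows(panel, pop, half_width=cfg.half_width)
            table.add(f"tajd_{pop}", d)
            table.add(f"neglogq_tajd_{pop}", ranking.neglog_rank(d, "low"))

    if "ihs" in statistics:
        for pop in pops:
            scores = haplo.ihs_scan(panel, pop)
            std = np.array([s.standardized for s in scores])
            table.add(f"ihs_std_{pop}", std)
            wprop = ranking.window_proportion(std, cfg.half_width,
                                              threshold=cfg.ihs_threshold,
                                              absolute=True)
            table.add(f"wprop_ihs_{pop}", wprop)
            table.add(f"neglogq_ihs_{pop}", ranking.neglog_rank(wprop, "high"))
            table.add(f"neglogp_ihs_{pop}", ranking.neglog_rank(wprop, "high"))

    if "fst" in statistics:
        for pa, pb in pairs:
            res = freq.fst_per_snp(panel, pa, pb)
            pair = f"{pa}_{pb}"
            table.add(f"fst_{pair}", res.fst)
            defined = np.isfinite(res.fst)
            if defined.sum() < 20:
                logger.info("skipping FST ranking for %s: %d defined SNPs",
                            pair, int(defined.sum()))
                continue
            cut5 = ranking.top_cutoff(res.fst, cfg.fst_cutoff_percentile)
            wprop = ranking.window_proportion(res.fst, cfg.half_width,
                                              threshold=cut5)
            table.add(f"wprop_fst_{pair}", wprop)
            table.add(f"neglogq_fst_{pair}", ranking.neglog_rank(wprop, "high"))
            table.add(f"neglogp_fst_{pair}", ranking.neglog_rank(res.fst, "high"))
            cut1 = ranking.top_cutoff(res.fst, cfg.top_flag_percentile)
            with np.errstate(invalid="ignore"):
                table.add(f"fst_top1_{pair}", defined & (res.fst > cut1))

    if "xpehh" in statistics:
        if len(pops) < 2:
            logger.info("skipping XP-EHH: needs two populations")
        else:
            for pa, pb in pairs:
                scores = haplo.xpehh_scan(panel, pa, pb)
                norm = np.array([s.normalized for s in scores])
                pair = f"{pa}_{pb}"
                table.add(f"xpehh_{pair}", norm)
                table.add(f"neglogp_xpehh_{pair}",
                          ranking.neglog_rank(norm, "high"))
    return table
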