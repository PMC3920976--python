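"""Empirical outlier ranking: window proportions, quantile cutoffs,
rank-based -log10(Q) scores, and gene-level empirical P values.

Genome scans of this family do not attach analytic significance to the
raw statistics; instead each statistic is ranked genome-wide and a SNP's
evidence is -log10 of its rank fraction Q = rank/N (3.0 means the most
extreme ~0.1%).  Haplotype and differentiation statistics are first
summarized as the proportion of a 51-SNP window (25 SNPs each side)
exceeding a fixed threshold (|iHS| > 2, or FST above the top-5% cutoff
of its population pair) before ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class RankConfig:
    """Knobs of the ranking stage, with the scan-standard defaults."""

    half_width: int = 25                  # SNPs each side -> 51-SNP window
    ihs_threshold: float = 2.0            # |iHS| above this counts as extreme
    fst_cutoff_percentile: float = 0.05   # top-5% defines a "significant" FST
    top_flag_percentile: float = 0.01     # top-1% FST SNPs get flagged
    gene_match_band: float = 0.20         # SNP-count band for gene empirical P

    def __post_init__(self) -> None:
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")
        for p in (self.fst_cutoff_percentile, self.top_flag_percentile):
            if not 0 < p < 1:
                raise ValueError("percentiles must lie in (0, 1)")


def window_proportion(values: np.ndarray, half_width: int,
                      exceed: np.ndarray | None = None,
                      threshold: float | None = None,
                      absolute: bool = False) -> np.ndarray:
    """Per-SNP fraction of its centered SNP window satisfying a predicate.

    The predicate is either a precomputed boolean array ``exceed`` or
    ``values > threshold`` (``|values| > threshold`` with ``absolute``).
    Windows are truncated at chromosome ends, never dropped; undefined
    (NaN) values are excluded from numerator and denominator.  A window
    with no defined member gives NaN.
    """
    values = np.asarray(values, dtype=float)
    defined = np.isfinite(values)
    if exceed is None:
        if threshold is None:
            raise ValueError("need either exceed or threshold")
        base = np.abs(values) if absolute else values
        with np.errstate(invalid="ignore"):
            exceed = base > threshold
    exceed = np.asarray(exceed, dtype=bool) & defined
    num = np.cumsum(np.concatenate(([0], exceed.astype(np.int64))))
    den = np.cumsum(np.concatenate(([0], defined.astype(np.int64))))
    m = values.size
    idx = np.arange(m)
    lo = np.maximum(0, idx - half_width)
    hi = np.minimum(m, idx + half_width + 1)
    d = den[hi] - den[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(d > 0, (num[hi] - num[lo]) / np.maximum(d, 1), np.nan)
    return out


def top_cutoff(values: np.ndarray, percentile: float) -> float:
    """Empirical top-percentile threshold (higher-is-extreme).

    Returns the value at the (1 - percentile) quantile such that the
    fraction of defined values strictly above it is <= percentile.
    Needs at least 20 defined values.
    """
    values = np.asarray(values, dtype=float)
    v = np.sort(values[np.isfinite(values)])[::-1]
    if v.size < 20:
        raise ValueError(f"top_cutoff needs >=20 defined values, got {v.size}")
    k = int(np.floor(percentile * v.size))
    return float(v[k])


def neglog_rank(values: np.ndarray, direction: str = "high") -> np.ndarray:
    """Rank-based -log10(Q) per SNP, Q = rank / N over defined values.

    The most extreme value gets rank 1; ``direction`` says whether high
    or low values are extreme (Tajima's D ranks low-is-extreme, iHS/FST
    window proportions high-is-extreme).  Ties take the maximum (least
    extreme) rank of their block, so tied scores are never overstated.
    Undefined inputs give NaN.
    """
    values = np.asarray(values, dtype=float)
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high' or 'low'")
    defined = np.isfinite(values)
    out = np.full(values.size, np.nan)
    v = values[defined]
    n = v.size
    if n == 0:
        return out
    key = -v if direction == "high" else v
    order = np.argsort(key, kind="stable")
    sorted_key = key[order]
    # max rank of the tied block = count of keys <= this key
    ranks_sorted = np.searchsorted(sorted_key, sorted_key, side="right")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = ranks_sorted
    out[defined] = -np.log10(ranks / n)
    return out


def gene_empirical_p(observed: float,
                     genome_windows: list[tuple[float, int]],
                     gene_snp_count: int,
                     match_band: float = 0.20,
                     min_matched: int = 100) -> float:
    """Gene-level empirical P against size-matched genome windows.

    The observed gene-window statistic is compared with genome windows
    whose SNP count is within ``match_band`` (default +/-20%) of the
    gene's; P = (1 + #matched >= observed) / (1 + #matched), the +1
    smoothing keeping P conservative and never zero.  Returns NaN when
    fewer than ``min_matched`` windows match.
    """
    lo = gene_snp_count * (1.0 - match_band)
    hi = gene_snp_count * (1.0 + match_band)
    matched = [s for s, c in genome_windows if lo <= c <= hi and np.isfinite(s)]
    if len(matched) < min_matched:
        return float("nan")
    n_ge = sum(1 for s in matched if s >= observed)
    return (1.0 + n_ge) / (1.0 + len(matched))
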