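"""Allele-frequency statistics: per-SNP Weir–Cockerham FST and Tajima's D.

FST uses the two-population haploid variance-component estimator of
Weir & Cockerham (1984): with r = 2 samples of n_i haplotypes at
frequencies p_i,

    n_bar = (n_1 + n_2) / 2
    n_c   = n_1 + n_2 - (n_1^2 + n_2^2) / (n_1 + n_2)
    p_bar = (n_1 p_1 + n_2 p_2) / (n_1 + n_2)
    s2    = sum_i n_i (p_i - p_bar)^2 / ((r - 1) n_bar)
    a     = (n_bar / n_c) * [s2 - (p_bar (1-p_bar) - s2 (r-1)/r) / (n_bar - 1)]
    b     = (n_bar / (n_bar - 1)) * [p_bar (1-p_bar) - s2 (r-1)/r]
    FST   = a / (a + b)

Haploid data carry no heterozygosity term, so the diploid c component is
absent.  Negative estimates are reported as computed; downstream ranking
treats them as no evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import MISSING, HaplotypePanel


@dataclass
class FstResult:
    pop_a: str
    pop_b: str
    fst: np.ndarray          # per SNP; NaN where undefined
    n_a: np.ndarray          # non-missing haplotype counts per SNP
    n_b: np.ndarray


@dataclass
class TajimaResult:
    chrom: str
    start: int               # half-open [start, end) in bp
    end: int
    n: int                   # haplotype sample size
    s: int                   # segregating sites
    pi: float                # mean pairwise differences
    d: float                 # NaN when undefined (S = 0)

    @property
    def defined(self) -> bool:
        return np.isfinite(self.d)


def derived_frequency(panel: HaplotypePanel, pop: str) -> np.ndarray:
    """Per-SNP derived-allele frequency over non-missing haplotypes.

    SNPs where the population has zero non-missing calls give NaN.
    """
    alleles = panel.alleles[panel.hap_indices(pop)]
    counts, n = _counts(alleles)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, counts / np.maximum(n, 1), np.nan)


def _counts(alleles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Derived counts and non-missing totals per SNP (complete-case)."""
    nonmiss = alleles != MISSING
    derived = (alleles == 1) & nonmiss
    return derived.sum(axis=0).astype(float), nonmiss.sum(axis=0).astype(float)


def fst_per_snp(panel: HaplotypePanel, pop_a: str, pop_b: str) -> FstResult:
    """Weir–Cockerham FST between two populations at every SNP.

    Undefined (NaN) where either population has <2 non-missing haplotypes
    or the SNP is monomorphic across both samples.
    """
    ca, na = _counts(panel.alleles[panel.hap_indices(pop_a)])
    cb, nb = _counts(panel.alleles[panel.hap_indices(pop_b)])
    fst = _wc_fst_haploid(ca, na, cb, nb)
    return FstResult(pop_a=pop_a, pop_b=pop_b, fst=fst,
                     n_a=na.astype(int), n_b=nb.astype(int))


def _wc_fst_haploid(ca, na, cb, nb) -> np.ndarray:
    ca, na, cb, nb = (np.asarray(x, dtype=float) for x in (ca, na, cb, nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = ca / na
        pb = cb / nb
        ntot = na + nb
        nbar = ntot / 2.0
        nc = ntot - (na**2 + nb**2) / ntot
        pbar = (ca + cb) / ntot
        s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / nbar  # r-1 = 1
        inner = pbar * (1.0 - pbar) - s2 / 2.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * inner
        fst = a / (a + b)
    bad = (na < 2) | (nb < 2)
    # monomorphic in both samples: a + b = 0, estimator undefined
    mono = ((ca + cb) == 0) | ((ca + cb) == ntot)
    fst = np.where(bad | mono, np.nan, fst)
    return fst


# ---------------------------------------------------------------------------
# Tajima's D

def _tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 normalizing constants for a sample of n haplotypes."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def pi_and_s(alleles: np.ndarray) -> tuple[float, int]:
    """Mean pairwise differences and segregating-site count.

    pi is the sum over sites of the per-site mean pairwise difference,
    computed over non-missing pairs at each site, which is robust to
    sporadic missingness.
    """
    counts, n = _counts(alleles)
    seg = (counts > 0) & (counts < n)
    s = int(seg.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        persite = 2.0 * counts * (n - counts) / (n * (n - 1.0))
    pi = float(np.nansum(np.where(n >= 2, persite, 0.0)))
    return pi, s


def tajimas_d(panel: HaplotypePanel, pop: str,
              start: int | None = None, end: int | None = None) -> TajimaResult:
    """Tajima's D for one population over a half-open bp window.

    D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)).  Flagged undefined (NaN)
    when the window has no segregating sites.  Requires >=4 haplotypes.
    """
    idx = panel.hap_indices(pop)
    if idx.size < 4:
        raise ValueError(f"Tajima's D needs >=4 haplotypes; {pop!r} has {idx.size}")
    if start is None:
        start = int(panel.positions[0])
    if end is None:
        end = int(panel.positions[-1]) + 1
    inwin = (panel.positions >= start) & (panel.positions < end)
    alleles = panel.alleles[np.ix_(idx, np.nonzero(inwin)[0])]
    return tajimas_d_from_matrix(alleles, panel.chrom, start, end)


def tajimas_d_from_matrix(alleles: np.ndarray, chrom: str = "1",
                          start: int = 0, end: int = 0) -> TajimaResult:
    """Tajima's D directly from a 0/1(/missing) haplotype matrix."""
    n = alleles.shape[0]
    pi, s = pi_and_s(alleles)
    if s == 0:
        d = float("nan")
    else:
        k = _tajima_constants(n)
        var = k["e1"] * s + k["e2"] * s * (s - 1)
        d = (pi - s / k["a1"]) / np.sqrt(var)
    return TajimaResult(chrom=chrom, start=start, end=end, n=n, s=s, pi=pi, d=d)


def tajimas_d_snp_windows(panel: HaplotypePanel, pop: str,
                          half_width: int = 25) -> np.ndarray:
    """Per-SNP Tajima's D over a centered window of 2*half_width+1 SNPs.

    Windows are truncated at chromosome ends.  This is the windowing used
    to feed D into the empirical ranking stage, matching the 51-SNP
    convention of the iHS window proportion.
    """
    idx = panel.hap_indices(pop)
    alleles = panel.alleles[idx]
    m = panel.n_variants
    out = np.full(m, np.nan)
    for j in range(m):
        lo = max(0, j - half_width)
        hi = min(m, j + half_width + 1)
        out[j] = tajimas_d_from_matrix(alleles[:, lo:hi]).d
    return out
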