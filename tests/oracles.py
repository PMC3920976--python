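"""Independent brute-force oracles used to pin down expected values.

Each oracle recomputes a statistic from its defining sums or by
exhaustive enumeration, sharing no code path with the implementation
it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def wc_fst_oracle(count_a: int, n_a: int, count_b: int, n_b: int) -> float:
    """Two-sample haploid Weir–Cockerham FST from the defining
    variance-component sums, evaluated long-hand."""
    r = 2
    p = [count_a / n_a, count_b / n_b]
    n = [n_a, n_b]
    nbar = sum(n) / r
    nc = (sum(n) - sum(x * x for x in n) / sum(n)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / sum(n)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    a = (nbar / nc) * (s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2)
    return a / (a + b)


def tajima_oracle(matrix: np.ndarray) -> float:
    """Tajima's D by enumerating every haplotype pair for pi and
    evaluating the constants from their defining sums."""
    n, _ = matrix.shape
    pairs = list(itertools.combinations(range(n), 2))
    pi = sum(int(np.sum(matrix[i] != matrix[j])) for i, j in pairs) / len(pairs)
    counts = matrix.sum(axis=0)
    s = int(np.sum((counts > 0) & (counts < n)))
    if s == 0:
        return float("nan")
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def ehh_oracle(alleles: np.ndarray, positions_cm: np.ndarray, core: int,
               allele_class: str, direction: str,
               truncate: bool = True, max_cm: float = 2.5
               ) -> list[tuple[float, float]]:
    """All-pairs EHH curve: at each extension SNP, count carrier pairs
    identical at every SNP between the core and that position
    (recomputed from scratch at every distance)."""
    col = alleles[:, core]
    if allele_class == "derived":
        carriers = [i for i in range(alleles.shape[0]) if col[i] == 1]
    elif allele_class == "ancestral":
        carriers = [i for i in range(alleles.shape[0]) if col[i] == 0]
    else:
        carriers = [i for i in range(alleles.shape[0]) if col[i] >= 0]
    if len(carriers) < 2:
        return []
    pts = [(0.0, 1.0)]
    if direction == "upstream":
        span = range(core - 1, -1, -1)
    else:
        span = range(core + 1, alleles.shape[1])
    visited: list[int] = []
    for j in span:
        dist = abs(positions_cm[j] - positions_cm[core])
        if dist > max_cm:
            break
        visited.append(j)
        # drop carriers with a missing call anywhere in the stretch
        live = [i for i in carriers
                if all(alleles[i, k] >= 0 for k in visited)]
        if len(live) < 2:
            break
        ident = 0
        total = 0
        for x, y in itertools.combinations(live, 2):
            total += 1
            if all(alleles[x, k] == alleles[y, k] for k in visited):
                ident += 1
        e = ident / total
        pts.append((float(dist), e))
        if truncate and e < 0.05:
            break
    return pts


def trapezoid_oracle(points: list[tuple[float, float]]) -> float:
    area = 0.0
    for (d0, e0), (d1, e1) in zip(points, points[1:]):
        area += 0.5 * (e0 + e1) * (d1 - d0)
    return area


def rank_oracle(values: np.ndarray, direction: str) -> np.ndarray:
    """-log10(rank/N) by explicit sort-and-count, ties -> max rank."""
    values = np.asarray(values, dtype=float)
    out = np.full(values.size, np.nan)
    defined = np.isfinite(values)
    v = values[defined]
    n = v.size
    res = []
    for x in v:
        if direction == "high":
            rank = int(np.sum(v >= x))
        else:
            rank = int(np.sum(v <= x))
        res.append(-math.log10(rank / n))
    out[defined] = res
    return out


def window_recount_oracle(values: np.ndarray, exceed: np.ndarray,
                          half_width: int) -> np.ndarray:
    """Direct per-SNP recount of the windowed exceedance proportion."""
    m = len(values)
    out = np.full(m, np.nan)
    for j in range(m):
        lo, hi = max(0, j - half_width), min(m, j + half_width + 1)
        num = den = 0
        for k in range(lo, hi):
            if np.isfinite(values[k]):
                den += 1
                num += bool(exceed[k])
        if den:
            out[j] = num / den
    return out
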