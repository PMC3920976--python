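"""Haplotype-length statistics: EHH decay, iHS, and XP-EHH.

Extended haplotype homozygosity (EHH) at genetic distance x from a core
SNP is the probability that two randomly drawn carrier haplotypes are
identical at every SNP between the core and x.  Integrating the EHH
curve over genetic distance gives iHH, a haplotype-length summary;
the log-ratio of iHH on the ancestral versus derived background,
standardized within derived-frequency bins, is the iHS.  XP-EHH compares
pooled-sample iHH between two populations, integrated to a shared
truncation point, and is z-normalized over the scanned SNP set.

Conventions (standard for genome scans of this family): EHH curves are
truncated once EHH drops below 0.05; iHS is scored only for SNPs with
derived frequency in [0.05, 0.95]; integration is over genetic distance
(cM), falling back to a constant cM/Mb conversion when no map is given;
extension is capped at 2.5 cM per side as a runtime guardrail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .panel import MISSING, HaplotypePanel

EHH_TRUNCATION = 0.05
FREQ_CLAMP = (0.05, 0.95)
MAX_EXTENSION_CM = 2.5
N_FREQ_BINS = 20


@dataclass
class EhhCurve:
    core: int
    allele_class: str            # "derived" | "ancestral" | "pooled"
    direction: str               # "upstream" | "downstream"
    points: list[tuple[float, float]]   # (cM distance from core, EHH)
    carrier_count: int
    truncated: str = ""          # "" | "threshold" | "chrom_end" | "cap" | "at_core"

    @property
    def defined(self) -> bool:
        return self.carrier_count >= 2


@dataclass
class IhsScore:
    core: int
    position: int
    derived_freq: float
    ihh_ancestral: float = np.nan
    ihh_derived: float = np.nan
    raw: float = np.nan
    standardized: float = np.nan

    @property
    def defined(self) -> bool:
        return np.isfinite(self.raw)


@dataclass
class XpehhScore:
    core: int
    position: int
    pop_a: str
    pop_b: str
    ihh_a: float = np.nan
    ihh_b: float = np.nan
    raw: float = np.nan
    normalized: float = np.nan

    @property
    def defined(self) -> bool:
        return np.isfinite(self.raw)


def _step_indices(n_variants: int, core: int, direction: str) -> range:
    if direction == "upstream":
        return range(core - 1, -1, -1)
    if direction == "downstream":
        return range(core + 1, n_variants)
    raise ValueError(f"direction must be upstream/downstream, got {direction!r}")


def _carriers(panel: HaplotypePanel, core: int, allele_class: str) -> np.ndarray:
    col = panel.alleles[:, core]
    if allele_class == "derived":
        return np.nonzero(col == 1)[0]
    if allele_class == "ancestral":
        return np.nonzero(col == 0)[0]
    if allele_class == "pooled":
        return np.nonzero(col != MISSING)[0]
    raise ValueError(f"unknown allele class {allele_class!r}")


@njit(cache=True)
def _ehh_steps_nb(sub, codes, threshold, truncate):  # pragma: no cover - jitted
    """Prefix-grouping EHH per extension step for a complete submatrix.

    ``sub`` holds the carriers' alleles at the extension SNPs in outward
    order; ``codes`` the group labels carried over from earlier steps.
    Group codes are refined SNP by SNP and compressed each step, so the
    running code stays bounded.  Returns the EHH series (stopping early
    below the threshold or at total breakdown into singletons) and the
    refined codes.
    """
    n, length = sub.shape
    denom = n * (n - 1) / 2.0
    out = np.empty(length, dtype=np.float64)
    stop = length
    for j in range(length):
        for i in range(n):
            codes[i] = codes[i] * 2 + sub[i, j]
        order = np.argsort(codes)
        new = np.empty(n, dtype=np.int64)
        cur = 0
        new[order[0]] = 0
        pairs = 0
        run = 1
        for t in range(1, n):
            if codes[order[t]] != codes[order[t - 1]]:
                pairs += run * (run - 1) // 2
                run = 1
                cur += 1
            else:
                run += 1
            new[order[t]] = cur
        pairs += run * (run - 1) // 2
        codes = new
        e = pairs / denom
        out[j] = e
        if (truncate and e < threshold) or pairs == 0:
            stop = j + 1
            break
    return out[:stop], codes


def ehh(panel: HaplotypePanel, core: int, allele_class: str,
        direction: str, truncate: bool = True,
        max_extension_cm: float = MAX_EXTENSION_CM) -> EhhCurve:
    """EHH decay curve outward from a core SNP for one allele class.

    The curve starts at (0, 1) and records, at each successive SNP, the
    fraction of carrier pairs identical over the whole stretch from the
    core.  Carriers with a missing call at an extension SNP are dropped
    from the carrier set (numerator and denominator) from that point on.
    With ``truncate`` the curve stops at the first point below the 0.05
    threshold (that point is kept so the integral reaches it).
    """
    carriers = _carriers(panel, core, allele_class)
    curve = EhhCurve(core=core, allele_class=allele_class, direction=direction,
                     points=[(0.0, 1.0)], carrier_count=int(carriers.size))
    if carriers.size < 2:
        curve.points = []
        return curve
    gmap = panel.map_positions()
    steps = np.fromiter(_step_indices(panel.n_variants, core, direction),
                        dtype=np.int64)
    dists = np.abs(gmap[steps] - gmap[core]) if steps.size else np.empty(0)
    capped = bool(steps.size) and bool((dists > max_extension_cm).any())
    within = steps[dists <= max_extension_cm] if steps.size else steps
    dists = dists[dists <= max_extension_cm] if steps.size else dists
    if within.size == 0:
        curve.truncated = "cap" if capped else "at_core"
        return curve
    if panel.has_missing:
        sub = panel.alleles[np.ix_(carriers, within)]
        if (sub == MISSING).any():
            return _ehh_with_missing(curve, sub, dists, truncate)
    # extract the extension in blocks so a quick truncation never pays
    # for the whole within-cap window
    codes = np.zeros(carriers.size, dtype=np.int64)
    chunks: list[np.ndarray] = []
    stopped = False
    for lo in range(0, within.size, 128):
        block = np.ascontiguousarray(
            panel.alleles[np.ix_(carriers, within[lo:lo + 128])])
        series, codes = _ehh_steps_nb(block, codes, EHH_TRUNCATION, truncate)
        chunks.append(series)
        if series.size < block.shape[1] or (series.size and series[-1] == 0.0) \
                or (truncate and series.size and series[-1] < EHH_TRUNCATION):
            stopped = True
            break
    series = np.concatenate(chunks) if chunks else np.empty(0)
    if not truncate and stopped:
        # all singleton groups: EHH stays 0 for the rest of the window
        series = np.concatenate([series,
                                 np.zeros(within.size - series.size)])
    curve.points.extend(zip(dists[:series.size].tolist(), series.tolist()))
    if truncate and stopped:
        curve.truncated = "threshold"
    else:
        curve.truncated = "cap" if capped else "chrom_end"
    return curve


def _ehh_with_missing(curve: EhhCurve, sub: np.ndarray, dists: np.ndarray,
                      truncate: bool) -> EhhCurve:
    """Stepwise fallback that drops carriers at their first missing call."""
    live = np.arange(sub.shape[0])
    codes = np.zeros(live.size, dtype=np.int64)
    for j in range(sub.shape[1]):
        alle = sub[live, j]
        keep = alle != MISSING
        if not keep.all():
            live = live[keep]
            codes = codes[keep]
            alle = alle[keep]
            if live.size < 2:
                curve.truncated = "threshold"
                return curve
        codes = codes * 2 + alle
        _, codes = np.unique(codes, return_inverse=True)
        e = _ehh_from_codes(codes)
        curve.points.append((float(dists[j]), float(e)))
        if truncate and e < EHH_TRUNCATION:
            curve.truncated = "threshold"
            return curve
    curve.truncated = "chrom_end"
    return curve


def _ehh_from_codes(codes: np.ndarray) -> float:
    n = codes.size
    counts = np.bincount(codes)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def integrate_ihh(curve: EhhCurve) -> float:
    """Trapezoidal area (cM units) under one directional EHH curve."""
    pts = curve.points
    if len(pts) < 2:
        return 0.0
    d = np.array([p[0] for p in pts])
    e = np.array([p[1] for p in pts])
    return float(np.trapezoid(e, d))


def _ihh_two_sided(panel: HaplotypePanel, core: int, allele_class: str) -> float:
    up = ehh(panel, core, allele_class, "upstream")
    down = ehh(panel, core, allele_class, "downstream")
    return integrate_ihh(up) + integrate_ihh(down)


def raw_ihs(panel: HaplotypePanel, core: int) -> IhsScore:
    """Unstandardized iHS = ln(iHH_ancestral / iHH_derived) at one SNP.

    Requires an ancestral-polarized core with derived frequency in
    [0.05, 0.95] and >=2 carriers on each background; otherwise the
    score is flagged undefined (NaN raw).
    """
    col = panel.alleles[:, core]
    nonmiss = col != MISSING
    n = int(nonmiss.sum())
    freq = float((col == 1).sum() / n) if n else np.nan
    score = IhsScore(core=core, position=int(panel.positions[core]),
                     derived_freq=freq)
    if not panel.polarized[core]:
        return score
    if not (FREQ_CLAMP[0] <= freq <= FREQ_CLAMP[1]):
        return score
    if (col == 1).sum() < 2 or (col == 0).sum() < 2:
        return score
    ihh_d = _ihh_two_sided(panel, core, "derived")
    ihh_a = _ihh_two_sided(panel, core, "ancestral")
    score.ihh_derived = ihh_d
    score.ihh_ancestral = ihh_a
    if ihh_d > 0 and ihh_a > 0:
        score.raw = float(np.log(ihh_a / ihh_d))
    return score


def ihs_scan(panel: HaplotypePanel, pop: str | None = None,
             standardize: bool = True) -> list[IhsScore]:
    """Raw (and optionally standardized) iHS at every scorable SNP."""
    sub = panel if pop is None else panel.subset_pop(pop)
    scores = [raw_ihs(sub, j) for j in range(sub.n_variants)]
    if standardize:
        standardize_ihs(scores)
    return scores


def standardize_ihs(scores: list[IhsScore],
                    n_bins: int = N_FREQ_BINS) -> list[IhsScore]:
    """Fill z-scores within derived-frequency bins (in place).

    Bins are equal-width on (0, 1); a bin needs >=2 defined raw scores,
    else its members stay undefined.  Standardization uses the bin's
    population moments, so each occupied bin ends at mean 0, sd 1.
    """
    raw = np.array([s.raw for s in scores])
    freq = np.array([s.derived_freq for s in scores])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.searchsorted(edges, freq, side="right") - 1, 0, n_bins - 1)
    defined = np.isfinite(raw)
    for b in range(n_bins):
        mask = defined & (which == b)
        if mask.sum() < 2:
            continue
        mu = raw[mask].mean()
        sd = raw[mask].std()
        if sd == 0:
            continue
        for i in np.nonzero(mask)[0]:
            scores[i].standardized = float((raw[i] - mu) / sd)
    return scores


# ---------------------------------------------------------------------------
# XP-EHH

def _pooled_series(panel: HaplotypePanel, core: int, direction: str,
                   max_extension_cm: float = MAX_EXTENSION_CM
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-sample EHH at every extension SNP out to the cM cap.

    Returns (distances, ehh values) including the core point, without
    threshold truncation — XP-EHH truncates at a point shared between
    the two populations, so the caller decides where to stop.
    """
    curve = ehh(panel, core, "pooled", direction, truncate=False,
                max_extension_cm=max_extension_cm)
    if not curve.points:
        return np.array([]), np.array([])
    d = np.array([p[0] for p in curve.points])
    e = np.array([p[1] for p in curve.points])
    return d, e


def xpehh(panel_a: HaplotypePanel, panel_b: HaplotypePanel,
          core: int) -> XpehhScore:
    """Raw XP-EHH = ln(iHH_A / iHH_B) at one core SNP.

    Both panels must share the variant grid.  Per direction, the pooled
    EHH of each population is integrated out to the first SNP where the
    pooled EHH has fallen below 0.05 in *both* populations (the shared
    truncation point), then the two-sided areas are compared.
    """
    if panel_a.n_variants != panel_b.n_variants:
        raise ValueError("XP-EHH requires a shared variant grid")
    pop_a = panel_a.pops[0] if panel_a.pops else "A"
    pop_b = panel_b.pops[0] if panel_b.pops else "B"
    score = XpehhScore(core=core, position=int(panel_a.positions[core]),
                       pop_a=pop_a, pop_b=pop_b)
    area_a = area_b = 0.0
    ok = True
    for direction in ("upstream", "downstream"):
        da, ea = _pooled_series(panel_a, core, direction)
        db, eb = _pooled_series(panel_b, core, direction)
        if da.size < 2 or db.size < 2:
            ok = False
            break
        k = min(da.size, db.size)
        below = np.nonzero((ea[:k] < EHH_TRUNCATION) & (eb[:k] < EHH_TRUNCATION))[0]
        stop = int(below[0]) + 1 if below.size else k
        area_a += float(np.trapezoid(ea[:stop], da[:stop]))
        area_b += float(np.trapezoid(eb[:stop], db[:stop]))
    if ok and area_a > 0 and area_b > 0:
        score.ihh_a = area_a
        score.ihh_b = area_b
        score.raw = float(np.log(area_a / area_b))
    return score


def xpehh_scan(panel: HaplotypePanel, pop_a: str, pop_b: str,
               normalize: bool = True) -> list[XpehhScore]:
    """XP-EHH at every SNP, z-normalized over the scanned set."""
    sub_a = panel.subset_pop(pop_a)
    sub_b = panel.subset_pop(pop_b)
    scores = [xpehh(sub_a, sub_b, j) for j in range(panel.n_variants)]
    for s in scores:
        s.pop_a, s.pop_b = pop_a, pop_b
    if normalize:
        normalize_xpehh(scores)
    return scores


def normalize_xpehh(scores: list[XpehhScore]) -> list[XpehhScore]:
    """Scale raw XP-EHH to mean 0, sd 1 over the defined scores (in place)."""
    raw = np.array([s.raw for s in scores])
    defined = np.isfinite(raw)
    if defined.sum() >= 2 and raw[defined].std() > 0:
        mu = raw[defined].mean()
        sd = raw[defined].std()
        for i in np.nonzero(defined)[0]:
            scores[i].normalized = float((raw[i] - mu) / sd)
    return scores
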