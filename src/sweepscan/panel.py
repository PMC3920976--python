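"""Core domain types for phased haplotype panels and candidate regions.

Coordinates are 1-based inclusive base pairs externally (the VCF
convention); interval queries use half-open ``[start, end)`` internally so
window arithmetic is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING: int = -1
"""Sentinel for a missing allele call in a haplotype matrix."""

DEFAULT_CM_PER_MB: float = 1.0
"""Fallback genetic-map density when no map is supplied."""


@dataclass
class HaplotypePanel:
    """A phased 0/1 haplotype matrix with positions and population labels.

    Parameters
    ----------
    chrom
        Chromosome identifier.
    positions
        1-based physical positions, strictly increasing, one per variant.
    alleles
        ``(n_haplotypes, n_variants)`` int8 matrix; 0 = ancestral,
        1 = derived, :data:`MISSING` = no call.
    pops
        Population label per haplotype row.
    map_cm
        Genetic-map position (centimorgans) per variant, non-decreasing.
        When absent, positions are converted at ``cm_per_mb``.
    polarized
        Per-variant flag: the ancestral allele is known, so 0/1 really
        mean ancestral/derived.  Unpolarized variants are usable for
        frequency statistics but not for iHS.
    """

    chrom: str
    positions: np.ndarray
    alleles: np.ndarray
    pops: list[str]
    map_cm: np.ndarray | None = None
    polarized: np.ndarray | None = None
    cm_per_mb: float = DEFAULT_CM_PER_MB
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.map_cm is not None:
            self.map_cm = np.asarray(self.map_cm, dtype=float)
        if self.polarized is None:
            self.polarized = np.ones(self.n_variants, dtype=bool)
        else:
            self.polarized = np.asarray(self.polarized, dtype=bool)
        self.pops = list(self.pops)
        if self.map_cm is None:
            self.metadata.setdefault("cm_per_mb_fallback", self.cm_per_mb)

    @property
    def has_missing(self) -> bool:
        """Whether any allele call is missing (cached after first check)."""
        if "_has_missing" not in self.metadata:
            self.metadata["_has_missing"] = bool((self.alleles == MISSING).any())
        return self.metadata["_has_missing"]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    @property
    def populations(self) -> list[str]:
        """Distinct population labels, in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.pops:
            seen.setdefault(p)
        return list(seen)

    def map_positions(self) -> np.ndarray:
        """Genetic-map positions in cM (from the map or the bp fallback)."""
        if self.map_cm is not None:
            return self.map_cm
        return self.positions / 1e6 * self.cm_per_mb

    def hap_indices(self, pop: str) -> np.ndarray:
        idx = np.array([i for i, p in enumerate(self.pops) if p == pop], dtype=np.intp)
        if idx.size == 0:
            raise KeyError(f"unknown population label: {pop!r}")
        return idx

    def subset_pop(self, pop: str) -> "HaplotypePanel":
        """Panel restricted to one population's haplotypes."""
        idx = self.hap_indices(pop)
        return HaplotypePanel(
            chrom=self.chrom,
            positions=self.positions.copy(),
            alleles=self.alleles[idx].copy(),
            pops=[self.pops[i] for i in idx],
            map_cm=None if self.map_cm is None else self.map_cm.copy(),
            polarized=self.polarized.copy(),
            cm_per_mb=self.cm_per_mb,
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class RegionSpec:
    """A candidate region: gene-region label, chromosome, center (Mb)."""

    name: str
    chrom: str
    center_mb: float

    @property
    def center_bp(self) -> int:
        return int(round(self.center_mb * 1e6))

    def canonical_name(self) -> str:
        """Case- and gene-order-insensitive identity for cross-list joins."""
        parts = sorted(g.strip().upper() for g in self.name.split(","))
        return ",".join(parts)


def validate_panel(panel: HaplotypePanel) -> list[str]:
    """Check panel invariants; return human-readable violation descriptors.

    An empty list means the panel is well formed.  Checks: strictly
    increasing positions, allele values in {0, 1, missing}, matrix/vector
    shape agreement, non-decreasing genetic map, and >=2 haplotypes per
    referenced population.
    """
    v: list[str] = []
    n_hap, n_var = panel.alleles.shape
    if panel.positions.shape[0] != n_var:
        v.append(f"positions length {panel.positions.shape[0]} != n_variants {n_var}")
    else:
        bad = np.nonzero(np.diff(panel.positions) <= 0)[0]
        for i in bad:
            v.append(f"non-increasing position at variant index {i + 1}")
    ok = (panel.alleles == 0) | (panel.alleles == 1) | (panel.alleles == MISSING)
    if not ok.all():
        rows, cols = np.nonzero(~ok)
        for r, c in zip(rows[:20], cols[:20]):
            v.append(f"invalid allele {panel.alleles[r, c]} at haplotype {r}, variant {c}")
    if len(panel.pops) != n_hap:
        v.append(f"pops length {len(panel.pops)} != n_haplotypes {n_hap}")
    else:
        for pop in panel.populations:
            n = sum(1 for p in panel.pops if p == pop)
            if n < 2:
                v.append(f"population {pop!r} has {n} haplotype(s); need >=2")
    if panel.map_cm is not None:
        if panel.map_cm.shape[0] != n_var:
            v.append("map_cm length mismatch")
        else:
            bad = np.nonzero(np.diff(panel.map_cm) < 0)[0]
            for i in bad:
                v.append(f"decreasing genetic map at variant index {i + 1}")
    if panel.polarized is not None and panel.polarized.shape[0] != n_var:
        v.append("polarized flag length mismatch")
    return v
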