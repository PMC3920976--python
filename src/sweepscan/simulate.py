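"""Synthetic data: forward Wright–Fisher haplotype simulation and
per-SNP statistic tables with planted signals.

The simulator is a discrete-generation haploid Wright–Fisher model with
recombination (random union of two parents with Poisson crossovers),
infinite-sites mutation on a base-pair grid, and optional viability
selection on a focal derived allele.  It is deliberately forward-in-time:
simple to reason about, exactly reproducible per seed, and adequate for
the desk-scale panels the statistics here are tested on (hundreds of
haplotypes, a few hundred kilobases).

Sweep runs condition on success by restarting from the post-burn-in
snapshot whenever the focal allele is lost (or overshoots the sampling
band), which biases toward successful sweeps — exactly the conditioning
wanted for power experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import HaplotypePanel
from .stats_table import SnpStatTable


@dataclass
class SweepSimConfig:
    """Parameters of one simulation run.

    ``n_haploid`` is the number of haploid genomes per population; the
    neutral burn-in runs ``6 * n_haploid`` generations, several haploid
    coalescent timescales, before any split or sweep.
    """

    n_haploid: int = 200
    length_bp: int = 500_000
    mu: float = 1e-7          # per site per generation
    rec: float = 1e-8         # per bp per generation (1e-8 = 1 cM/Mb)
    s: float = 0.0            # selection coefficient on the focal allele
    init_copies: int = 1      # copies at sweep introduction
    target_freq: float = 0.7  # sample when focal frequency hits this +/- band
    target_band: float = 0.05
    n_pops: int = 1
    split_time: int = 0       # generations of independent evolution post split
    sample_size: int = 100    # haplotypes sampled per population
    pop_labels: tuple = ("POP1", "POP2", "POP3", "POP4")
    seed: int = 0
    max_restarts: int = 200

    def __post_init__(self) -> None:
        if min(self.mu, self.rec) < 0 or self.s < 0:
            raise ValueError("rates and s must be >= 0")
        if not 0 < self.target_freq <= 1:
            raise ValueError("target_freq must lie in (0, 1]")
        if self.sample_size > self.n_haploid:
            raise ValueError("cannot sample more haplotypes than the population holds")
        if self.n_pops > len(self.pop_labels):
            raise ValueError("not enough population labels")


class _Deme:
    """One population's haplotype matrix with a shared position registry."""

    def __init__(self, n: int, positions: list[int], mat: np.ndarray):
        self.n = n
        self.positions = positions          # bp per column, unsorted
        self.mat = mat                      # (n, n_sites) int8

    def copy(self) -> "_Deme":
        return _Deme(self.n, list(self.positions), self.mat.copy())


def _next_generation(deme: _Deme, cfg: SweepSimConfig, rng: np.random.Generator,
                     used: set, focal_pos: int | None) -> None:
    n, L = deme.n, cfg.length_bp
    s_local = cfg.s if focal_pos is not None and focal_pos in deme.positions else 0.0
    if s_local > 0:
        col = deme.positions.index(focal_pos)
        w = 1.0 + s_local * deme.mat[:, col].astype(float)
        probs = w / w.sum()
        p1 = rng.choice(n, size=n, p=probs)
        p2 = rng.choice(n, size=n, p=probs)
    else:
        p1 = rng.integers(0, n, size=n)
        p2 = rng.integers(0, n, size=n)
    n_cross = rng.poisson(cfg.rec * L, size=n)
    children = deme.mat[p1].copy()
    rec_idx = np.nonzero(n_cross > 0)[0]
    if rec_idx.size and deme.positions:
        pos = np.array(deme.positions)
        for i in rec_idx:
            cuts = np.sort(rng.integers(1, L + 1, size=n_cross[i]))
            # segment parity: which parent contributes at each site
            seg = np.searchsorted(cuts, pos, side="right") % 2
            if rng.integers(0, 2):
                seg = 1 - seg
            take2 = seg == 1
            children[i, take2] = deme.mat[p2[i], take2]
    deme.mat = children
    n_mut = rng.poisson(cfg.mu * L * n)
    if n_mut:
        new_cols = np.zeros((n, n_mut), dtype=np.int8)
        kept = 0
        for _ in range(n_mut):
            for _try in range(100):
                bp = int(rng.integers(1, L + 1))
                if bp not in used:
                    break
            else:
                continue
            used.add(bp)
            deme.positions.append(bp)
            new_cols[rng.integers(0, n), kept] = 1
            kept += 1
        if kept:
            deme.mat = np.concatenate([deme.mat, new_cols[:, :kept]], axis=1)


def _prune(deme: _Deme, used: set, keep_pos: int | None = None) -> None:
    """Drop columns fixed or lost in this deme, freeing their positions."""
    if not deme.positions:
        return
    counts = deme.mat.sum(axis=0)
    poly = (counts > 0) & (counts < deme.n)
    if keep_pos is not None and keep_pos in deme.positions:
        poly[deme.positions.index(keep_pos)] = True
    if poly.all():
        return
    for j in np.nonzero(~poly)[0]:
        used.discard(deme.positions[j])
    deme.positions = [p for p, k in zip(deme.positions, poly) if k]
    deme.mat = deme.mat[:, poly]


def _focal_freq(deme: _Deme, focal_pos: int) -> float:
    if focal_pos not in deme.positions:
        return 0.0
    return float(deme.mat[:, deme.positions.index(focal_pos)].mean())


def simulate_panel(cfg: SweepSimConfig) -> tuple[HaplotypePanel, int | None]:
    """Run the configured simulation and sample a haplotype panel.

    Returns the panel and the focal SNP's column index in the panel
    (None for neutral runs).  The same config (including seed) always
    yields a bit-identical panel.
    """
    rng = np.random.default_rng(cfg.seed)
    used: set[int] = set()
    deme = _Deme(cfg.n_haploid, [], np.zeros((cfg.n_haploid, 0), dtype=np.int8))
    burn_in = 6 * cfg.n_haploid
    for g in range(burn_in):
        _next_generation(deme, cfg, rng, used, None)
        if g % 25 == 24:
            _prune(deme, used)
    _prune(deme, used)

    focal_pos: int | None = None
    if cfg.n_pops > 1:
        demes = [deme] + [deme.copy() for _ in range(cfg.n_pops - 1)]
        if cfg.s > 0:
            focal_pos = _run_sweep(demes[0], cfg, rng, used,
                                   extra_demes=demes[1:])
        else:
            # no per-deme pruning after the split: a variant lost or fixed
            # in one deme may still differ across demes, and that
            # between-population difference is the FST signal
            for _ in range(cfg.split_time):
                for d in demes:
                    _next_generation(d, cfg, rng, used, None)
    else:
        demes = [deme]
        if cfg.s > 0:
            focal_pos = _run_sweep(deme, cfg, rng, used)
    return _sample(demes, cfg, rng, focal_pos)


def _run_sweep(deme: _Deme, cfg: SweepSimConfig, rng: np.random.Generator,
               used: set, extra_demes: list | None = None) -> int:
    """Introduce the focal allele and evolve until it enters the band.

    Restarts from the pre-sweep snapshot when the allele is lost or
    overshoots the sampling band; fails loudly after max_restarts.
    Other demes (if any) evolve neutrally for the same number of
    generations as the successful sweep took.
    """
    lo = cfg.target_freq - cfg.target_band
    hi = min(1.0, cfg.target_freq + cfg.target_band)
    snapshot = deme.copy()
    used_snapshot = set(used)
    for attempt in range(cfg.max_restarts + 1):
        work = snapshot.copy()
        w_used = set(used_snapshot)
        for _try in range(1000):
            focal_pos = int(rng.integers(cfg.length_bp // 4,
                                         3 * cfg.length_bp // 4))
            if focal_pos not in w_used:
                break
        w_used.add(focal_pos)
        col = np.zeros((work.n, 1), dtype=np.int8)
        carriers = rng.choice(work.n, size=cfg.init_copies, replace=False)
        col[carriers, 0] = 1
        work.positions.append(focal_pos)
        work.mat = np.concatenate([work.mat, col], axis=1)
        gens = 0
        max_gens = 200 * max(1, int(1.0 / max(cfg.s, 1e-9)))
        ok = False
        while gens < max_gens:
            _next_generation(work, cfg, rng, w_used, focal_pos)
            gens += 1
            f = _focal_freq(work, focal_pos)
            if f == 0.0 or f > hi:
                break
            if lo <= f <= hi:
                ok = True
                break
            if gens % 25 == 0 and not extra_demes:
                _prune(work, w_used, keep_pos=focal_pos)
        if ok:
            deme.positions = work.positions
            deme.mat = work.mat
            deme.n = work.n
            used.clear()
            used.update(w_used)
            if extra_demes:
                for d in extra_demes:
                    for _ in range(gens):
                        _next_generation(d, cfg, rng, used, None)
            else:
                _prune(deme, used, keep_pos=focal_pos)
            return focal_pos
    raise RuntimeError(
        f"sweep lost/overshot in all {cfg.max_restarts} restarts (seed={cfg.seed})")


def _sample(demes: list[_Deme], cfg: SweepSimConfig,
            rng: np.random.Generator,
            focal_pos: int | None) -> tuple[HaplotypePanel, int | None]:
    all_pos = sorted(set().union(*[d.positions for d in demes]))
    pos_index = {p: i for i, p in enumerate(all_pos)}
    blocks = []
    pops: list[str] = []
    for k, d in enumerate(demes):
        take = rng.choice(d.n, size=cfg.sample_size, replace=False)
        block = np.zeros((cfg.sample_size, len(all_pos)), dtype=np.int8)
        if d.positions:
            cols = [pos_index[p] for p in d.positions]
            block[:, cols] = d.mat[take]
        blocks.append(block)
        pops.extend([cfg.pop_labels[k]] * cfg.sample_size)
    alleles = np.vstack(blocks)
    counts = alleles.sum(axis=0)
    poly = (counts > 0) & (counts < alleles.shape[0])
    if focal_pos is not None:
        poly[pos_index[focal_pos]] = True
    alleles = alleles[:, poly]
    positions = np.array(all_pos, dtype=np.int64)[poly]
    map_cm = positions * cfg.rec * 100.0  # Morgans/bp -> cM
    panel = HaplotypePanel(
        chrom="1", positions=positions, alleles=alleles, pops=pops,
        map_cm=map_cm,
        metadata={"simulator": "forward-wright-fisher", "seed": cfg.seed},
    )
    focal_idx = None
    if focal_pos is not None:
        focal_idx = int(np.searchsorted(positions, focal_pos))
        panel.metadata["focal_position"] = focal_pos
    return panel, focal_idx


# ---------------------------------------------------------------------------
# Planted statistic tables

def simulate_stat_table(n_snps: int,
                        planted: list[tuple[tuple[int, int], str, float]],
                        noise_law: dict[str, tuple],
                        seed: int,
                        chrom: str = "1",
                        span_bp: int | None = None) -> SnpStatTable:
    """Per-SNP statistic table: background noise plus planted signals.

    ``noise_law`` maps column name to ("uniform", lo, hi) or
    ("expon", scale); ``planted`` entries are ((start, end), column,
    value) with half-open bp intervals whose SNPs are overwritten by the
    value.  Overlapping plants on one column, or a plant interval with no
    SNP, fail loudly.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    span = span_bp or n_snps * 1000
    positions = np.sort(rng.choice(np.arange(1, span + 1), size=n_snps,
                                   replace=False))
    table = SnpStatTable.from_positions(chrom, positions)
    for col, law in noise_law.items():
        kind = law[0]
        if kind == "uniform":
            vals = rng.uniform(law[1], law[2], size=n_snps)
        elif kind == "expon":
            vals = rng.exponential(law[1], size=n_snps)
        else:
            raise ValueError(f"unknown noise law {kind!r}")
        table.add(col, vals)
    seen: dict[str, list[tuple[int, int]]] = {}
    for (start, end), col, value in planted:
        for s0, e0 in seen.get(col, []):
            if start < e0 and s0 < end:
                raise ValueError(f"overlapping plants on column {col!r}")
        seen.setdefault(col, []).append((start, end))
        mask = (positions >= start) & (positions < end)
        if not mask.any():
            raise ValueError(f"plant interval [{start}, {end}) contains no SNP")
        vals = table.df[col].to_numpy(dtype=float)
        vals[mask] = value
        table.df[col] = vals
    return table
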