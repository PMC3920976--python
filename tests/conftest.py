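from pathlib import Path

import numpy as np
import pytest

from sweepscan.io import read_haplotype_tsv
from sweepscan.panel import HaplotypePanel
from sweepscan.simulate import SweepSimConfig, simulate_panel

DATA = Path(__file__).parent / "data"


def random_panel(rng: np.random.Generator, n_hap: int, n_snp: int,
                 pops: list[str] | None = None,
                 missing_rate: float = 0.0) -> HaplotypePanel:
    """Uniform-random 0/1 panel with sorted random positions."""
    alleles = rng.integers(0, 2, size=(n_hap, n_snp)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(alleles.shape) < missing_rate
        alleles[mask] = -1
    positions = np.sort(rng.choice(np.arange(1, 10_000_000), size=n_snp,
                                   replace=False))
    if pops is None:
        pops = ["POP1"] * n_hap
    return HaplotypePanel("1", positions, alleles, pops)


@pytest.fixture
def tajima_toy_panel():
    return read_haplotype_tsv(DATA / "tajima_toy_panel.tsv")


@pytest.fixture
def ihs_sweep_panel():
    return read_haplotype_tsv(DATA / "ihs_sweep_panel.tsv")


@pytest.fixture(scope="session")
def neutral_replicates():
    """Neutral single-population panels shared by distributional tests.

    Twelve forward Wright-Fisher replicates at mutation rate 2e-7/bp,
    recombination 1e-8/bp (1 cM/Mb) over 2.5 Mb, 200 haploids, sampling
    100 haplotypes -- together they provide several thousand scoreable
    SNPs and >200 non-overlapping 51-SNP windows.
    """
    panels = []
    for i in range(12):
        cfg = SweepSimConfig(n_haploid=200, length_bp=2_500_000, mu=2e-7,
                             rec=1e-8, sample_size=100, seed=100 + i)
        panel, _ = simulate_panel(cfg)
        panels.append(panel)
    return panels
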