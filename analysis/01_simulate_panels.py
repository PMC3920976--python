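#!/usr/bin/env python
"""Simulate the example haplotype panels used by the downstream steps.

Writes to results/panels/:
    neutral.vcf        single population, no selection
    sweep.vcf          partial sweep (s = 0.05, target frequency 0.7)
                       with a .truth.tsv recording the focal SNP
    two_pop.vcf        two populations separated 120 generations ago
    *.pops.tsv         sample -> population maps for `sweepscan scan`
"""

from pathlib import Path

from sweepscan.io import sample_pop_map_for, write_vcf
from sweepscan.simulate import SweepSimConfig, simulate_panel

OUT = Path(__file__).resolve().parent.parent / "results" / "panels"

CONFIGS = {
    "neutral": SweepSimConfig(n_haploid=200, length_bp=500_000, mu=2e-7,
                              sample_size=100, seed=1),
    "sweep": SweepSimConfig(n_haploid=500, length_bp=1_000_000, mu=2e-8,
                            rec=2e-8, s=0.05, target_freq=0.7,
                            sample_size=100, seed=2),
    "two_pop": SweepSimConfig(n_haploid=200, length_bp=500_000, mu=2e-7,
                              n_pops=2, split_time=120, sample_size=100,
                              seed=3),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, cfg in CONFIGS.items():
        panel, focal = simulate_panel(cfg)
        vcf = OUT / f"{name}.vcf"
        write_vcf(panel, vcf)
        with open(OUT / f"{name}.pops.tsv", "w") as fh:
            for sample, pop in sample_pop_map_for(panel).items():
                fh.write(f"{sample}\t{pop}\n")
        if focal is not None:
            with open(OUT / f"{name}.truth.tsv", "w") as fh:
                fh.write("key\tvalue\n")
                fh.write(f"focal_index\t{focal}\n")
                fh.write(f"focal_position\t{panel.positions[focal]}\n")
        print(f"{name}: {panel.n_variants} variants, "
              f"{panel.n_haplotypes} haplotypes -> {vcf}")


if __name__ == "__main__":
    main()
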