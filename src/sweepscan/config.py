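"""Run configuration: a single serializable record of everything a run
needs, written back into every output directory for auditability."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .evidence import EvidenceRuleSet
from .ranking import RankConfig


@dataclass
class RunConfig:
    vcf: str | None = None
    haplotype_tsv: str | None = None
    sample_pop_map: dict = field(default_factory=dict)
    regions: str | None = None
    statistics: list = field(default_factory=lambda: ["fst", "tajd", "ihs", "xpehh"])
    rank: RankConfig = field(default_factory=RankConfig)
    rules: EvidenceRuleSet = field(default_factory=EvidenceRuleSet)
    region_width_bp: int = 1_000_000
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        if "rank" in raw and isinstance(raw["rank"], dict):
            raw["rank"] = RankConfig(**raw["rank"])
        if "rules" in raw and isinstance(raw["rules"], dict):
            raw["rules"] = EvidenceRuleSet(**raw["rules"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def write_copy(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        p = out / "run_config.yaml"
        self.to_yaml(p)
        return p
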