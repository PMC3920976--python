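"""Per-SNP statistic table shared by the ranking and region stages.

A thin wrapper over a pandas DataFrame with one row per SNP and a
column-naming convention the region stage can introspect:

======================  =====================================================
column                  meaning
======================  =====================================================
``chrom, pos, rsid``    coordinates (pos is 1-based bp)
``freq_<pop>``          derived-allele frequency
``fst_<A>_<B>``         per-SNP Weir–Cockerham FST for a population pair
``ihs_std_<pop>``       standardized iHS
``tajd_<pop>``          window-assigned Tajima's D
``wprop_ihs_<pop>``     51-SNP window proportion with |iHS| > 2
``wprop_fst_<A>_<B>``   window proportion with FST above the pair's cutoff
``xpehh_<A>_<B>``       normalized XP-EHH
``neglogq_<stat>_<l>``  empirical -log10(rank/N) score (HapMap-browser style)
``neglogp_<stat>_<l>``  empirical -log10 P (HGDP-browser style)
``fst_top1_<A>_<B>``    boolean: SNP in the top 1% of the pair's FST
======================  =====================================================

``<stat>`` is one of ``ihs``, ``tajd``, ``fst``, ``xpehh`` (no underscore)
and ``<l>`` a population label or ``<A>_<B>`` pair.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SCORE_PREFIXES = ("neglogq_", "neglogp_")


class SnpStatTable:
    """Per-SNP statistics keyed by (chrom, pos, rsid)."""

    def __init__(self, df: pd.DataFrame):
        for col in ("chrom", "pos"):
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        if "rsid" not in df.columns:
            df = df.copy()
            df["rsid"] = [f"snp{i}" for i in range(len(df))]
        self.df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        self._check()

    def _check(self) -> None:
        for col in self.df.columns:
            vals = self.df[col]
            if col.startswith(SCORE_PREFIXES):
                if (vals.dropna() < 0).any():
                    raise ValueError(f"negative -log score in {col}")
            elif col.startswith("wprop_"):
                bad = vals.dropna()
                if ((bad < 0) | (bad > 1)).any():
                    raise ValueError(f"window proportion outside [0,1] in {col}")
            elif col.startswith("fst_") and not col.startswith("fst_top1_"):
                if (vals.dropna() > 1 + 1e-12).any():
                    raise ValueError(f"FST > 1 in {col}")

    @classmethod
    def from_positions(cls, chrom: str, positions: np.ndarray,
                       rsids: list[str] | None = None) -> "SnpStatTable":
        df = pd.DataFrame({"chrom": str(chrom), "pos": np.asarray(positions)})
        if rsids is not None:
            df["rsid"] = rsids
        return cls(df)

    def add(self, column: str, values) -> None:
        self.df[column] = values
        self._check()

    def score_columns(self, kind: str) -> dict[tuple[str, str], str]:
        """Map (statistic, label) -> column for 'q' or 'p' -log scores."""
        prefix = {"q": "neglogq_", "p": "neglogp_"}[kind]
        out: dict[tuple[str, str], str] = {}
        for col in self.df.columns:
            if col.startswith(prefix):
                stat, _, label = col[len(prefix):].partition("_")
                out[(stat, label)] = col
        return out

    def top1_flag_columns(self) -> dict[str, str]:
        """Map population-pair label -> boolean top-1% FST column."""
        return {col[len("fst_top1_"):]: col
                for col in self.df.columns if col.startswith("fst_top1_")}

    def in_interval(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """Rows on ``chrom`` with pos in half-open [start, end)."""
        m = (self.df["chrom"].astype(str) == str(chrom)) \
            & (self.df["pos"] >= start) & (self.df["pos"] < end)
        return self.df[m]

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "SnpStatTable":
        return cls(pd.read_csv(path, sep="\t", na_values=["NA"],
                               dtype={"chrom": str}))

    def __len__(self) -> int:
        return len(self.df)
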