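"""Readers and writers: phased VCF, haplotype-matrix TSV, region lists,
evidence reports, and the packaged example tables.

The packaged tables under ``data/`` transcribe published genome-scan
browser queries for 74 SLE-associated candidate regions: the region
list itself, the per-region evidence extracted from the HapMap-based
scan browser (windowed -log10(Q) maxima for iHS, Tajima's D and FST,
top-1% FST SNP values, gene empirical P), and the per-region maxima
from the HGDP-based scan browser (-log10 empirical P for FST, iHS and
XP-EHH).  They exercise the region-evidence stage without any external
download.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .evidence import RegionEvidence, concordance  # noqa: F401 (re-export)
from .panel import MISSING, HaplotypePanel, RegionSpec

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path, sample_pop_map: dict[str, str]) -> HaplotypePanel:
    """Load a phased biallelic VCF into a haplotype panel.

    Each diploid sample contributes two haplotype rows.  An ``AA=``
    INFO tag sets polarization: records whose ancestral allele equals
    ALT are flipped so 1 always means derived; records with no AA tag
    are kept unpolarized.  Unphased, multiallelic or duplicate-position
    records are skipped (counts logged).  All samples must appear in
    ``sample_pop_map``.
    """
    import pysam

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    for s in samples:
        if s not in sample_pop_map:
            raise KeyError(f"sample {s!r} absent from population map")
    pops = [p for s in samples for p in (sample_pop_map[s], sample_pop_map[s])]
    positions: list[int] = []
    rows: list[np.ndarray] = []
    polarized: list[bool] = []
    chrom = None
    skipped = {"unphased": 0, "multiallelic": 0, "duplicate": 0}
    flipped = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            skipped["multiallelic"] += 1
            continue
        if chrom is None:
            chrom = rec.chrom
        if positions and rec.pos <= positions[-1]:
            skipped["duplicate"] += 1
            continue
        calls = np.full(2 * len(samples), MISSING, dtype=np.int8)
        ok = True
        for i, s in enumerate(samples):
            sv = rec.samples[s]
            gt = sv.get("GT")
            if gt is None or len(gt) != 2:
                ok = False
                break
            if None not in gt and not sv.phased:
                ok = False
                break
            for k in (0, 1):
                if gt[k] is not None:
                    calls[2 * i + k] = gt[k]
        if not ok:
            skipped["unphased"] += 1
            continue
        aa = rec.info.get("AA")
        if isinstance(aa, tuple):
            aa = aa[0]
        pol = aa is not None and str(aa).upper() in (rec.ref.upper(),
                                                     rec.alts[0].upper())
        if pol and str(aa).upper() == rec.alts[0].upper():
            present = calls != MISSING
            calls[present] = 1 - calls[present]
            flipped += 1
        positions.append(rec.pos)
        rows.append(calls)
        polarized.append(pol)
    vf.close()
    if not rows:
        raise ValueError(f"no usable phased biallelic records in {path}")
    logger.info("read_vcf %s: %d variants, %d flipped to derived, skipped %s",
                path.name, len(rows), flipped, skipped)
    return HaplotypePanel(
        chrom=str(chrom), positions=np.array(positions, dtype=np.int64),
        alleles=np.array(rows, dtype=np.int8).T.copy(), pops=pops,
        polarized=np.array(polarized, dtype=bool),
        metadata={"source": str(path), "skipped": skipped, "flipped": flipped},
    )


def write_vcf(panel: HaplotypePanel, path, sample_prefix: str = "S") -> None:
    """Write a panel as a plain-text phased VCF (pairs of haplotypes
    become diploid samples; odd row counts raise).

    Output is byte-deterministic for a given panel.  The ancestral
    allele is emitted as ``AA=A`` (REF) for polarized variants.
    """
    if panel.n_haplotypes % 2:
        raise ValueError("VCF output needs an even number of haplotypes")
    n_samp = panel.n_haplotypes // 2
    names = [f"{sample_prefix}{i:04d}" for i in range(n_samp)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for j in range(panel.n_variants):
            info = "AA=A" if panel.polarized[j] else "."
            gts = []
            for i in range(n_samp):
                a, b = panel.alleles[2 * i, j], panel.alleles[2 * i + 1, j]
                gts.append(f"{'.' if a == MISSING else a}|{'.' if b == MISSING else b}")
            fh.write(f"{panel.chrom}\t{panel.positions[j]}\tsnp{j}\tA\tT\t.\tPASS\t"
                     f"{info}\tGT\t" + "\t".join(gts) + "\n")


def sample_pop_map_for(panel: HaplotypePanel, sample_prefix: str = "S") -> dict[str, str]:
    """Population map matching :func:`write_vcf` sample naming."""
    return {f"{sample_prefix}{i:04d}": panel.pops[2 * i]
            for i in range(panel.n_haplotypes // 2)}


# ---------------------------------------------------------------------------
# Haplotype-matrix TSV (small fixtures)

def read_haplotype_tsv(path) -> HaplotypePanel:
    """Read the compact haplotype dialect: a header line
    ``#positions<TAB>p1<TAB>p2...`` then ``pop<TAB>hapID<TAB>0/1 string``
    rows ('.' = missing call).
    """
    pops, rows = [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "#positions":
            raise ValueError("haplotype TSV must start with '#positions'")
        positions = np.array([int(x) for x in header[1:]], dtype=np.int64)
        for line in fh:
            if not line.strip():
                continue
            pop, _hap, alleles = line.rstrip("\n").split("\t")
            pops.append(pop)
            rows.append([MISSING if c == "." else int(c) for c in alleles])
    return HaplotypePanel(chrom="1", positions=positions,
                          alleles=np.array(rows, dtype=np.int8), pops=pops)


def write_haplotype_tsv(panel: HaplotypePanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("#positions\t" + "\t".join(map(str, panel.positions)) + "\n")
        for i in range(panel.n_haplotypes):
            s = "".join("." if a == MISSING else str(a) for a in panel.alleles[i])
            fh.write(f"{panel.pops[i]}\thap{i}\t{s}\n")


# ---------------------------------------------------------------------------
# Region lists

def read_regions(path) -> list[RegionSpec]:
    """Read a candidate-region TSV (columns name, chrom, pos_mb)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("name", "chrom", "pos_mb"):
        if col not in df.columns:
            raise ValueError(f"region list missing column {col!r}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(RegionSpec(name=str(row["name"]), chrom=str(row["chrom"]),
                                  center_mb=float(row["pos_mb"])))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed region row at line {i + 2}: {exc}") from exc
    names = [r.canonical_name() for r in out]
    if len(set(names)) != len(names):
        raise ValueError("duplicate region names in list")
    return out


def write_regions(regions: list[RegionSpec], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tchrom\tpos_mb\n")
        for r in regions:
            fh.write(f"{r.name}\t{r.chrom}\t{r.center_mb:g}\n")


# ---------------------------------------------------------------------------
# Evidence reports

_EV_COLUMNS = [
    "region", "chrom", "center_mb", "n_snps",
    "neglogq_ihs", "neglogq_ihs_pop", "neglogq_tajd", "neglogq_tajd_pop",
    "neglogq_fst", "neglogq_fst_pop",
    "neglogp_fst", "neglogp_fst_pop", "neglogp_ihs", "neglogp_ihs_pop",
    "neglogp_xpehh", "neglogp_xpehh_pop",
    "top1_fst_hits", "min_gene_p", "min_gene_p_pop",
    "qualifies", "reasons",
]


def evidence_to_frame(evidence: list[RegionEvidence]) -> pd.DataFrame:
    rows = []
    for ev in evidence:
        row = {c: np.nan for c in _EV_COLUMNS}
        row.update(region=ev.region.name, chrom=ev.region.chrom,
                   center_mb=ev.region.center_mb, n_snps=ev.n_snps,
                   qualifies=ev.qualifies, reasons=";".join(ev.reasons))
        for stat, (val, label) in ev.max_neglogq.items():
            row[f"neglogq_{stat}"] = val
            row[f"neglogq_{stat}_pop"] = label
        for stat, (val, label) in ev.max_neglogp.items():
            row[f"neglogp_{stat}"] = val
            row[f"neglogp_{stat}_pop"] = label
        if ev.top1pct_fst_hits:
            row["top1_fst_hits"] = ";".join(
                f"{rsid}:{val:g}:{pair}" for rsid, val, pair in ev.top1pct_fst_hits)
        if ev.min_gene_p is not None:
            row["min_gene_p"] = ev.min_gene_p[0]
            row["min_gene_p_pop"] = ev.min_gene_p[1]
        rows.append(row)
    return pd.DataFrame(rows, columns=_EV_COLUMNS)


def write_evidence_tsv(evidence: list[RegionEvidence], path) -> None:
    evidence_to_frame(evidence).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_evidence_tsv(path) -> list[RegionEvidence]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str})
    out = []
    for _, row in df.iterrows():
        ev = RegionEvidence(region=RegionSpec(name=str(row["region"]),
                                              chrom=str(row["chrom"]),
                                              center_mb=float(row["center_mb"])))
        ev.n_snps = int(row["n_snps"]) if pd.notna(row.get("n_snps")) else 0
        for kind, store in (("neglogq", ev.max_neglogq), ("neglogp", ev.max_neglogp)):
            for stat in ("ihs", "tajd", "fst", "xpehh"):
                col = f"{kind}_{stat}"
                if col in df.columns and pd.notna(row[col]):
                    label = row.get(f"{col}_pop")
                    store[stat] = (float(row[col]),
                                   "" if pd.isna(label) else str(label))
        hits = row.get("top1_fst_hits")
        if isinstance(hits, str) and hits:
            for h in hits.split(";"):
                rsid, val, pair = h.split(":")
                ev.top1pct_fst_hits.append((rsid, float(val), pair))
        if pd.notna(row.get("min_gene_p")):
            pop = row.get("min_gene_p_pop")
            ev.min_gene_p = (float(row["min_gene_p"]),
                             "" if pd.isna(pop) else str(pop))
        if "qualifies" in df.columns and pd.notna(row["qualifies"]):
            ev.qualifies = bool(row["qualifies"])
            r = row.get("reasons")
            ev.reasons = r.split(";") if isinstance(r, str) and r else []
        out.append(ev)
    return out


def write_reports(evidence_lists: dict[str, list[RegionEvidence]],
                  concordance_table: pd.DataFrame | None,
                  out_dir) -> list[Path]:
    """Write one evidence TSV per named list plus the concordance table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, evs in evidence_lists.items():
        p = out_dir / f"evidence_{name}.tsv"
        write_evidence_tsv(evs, p)
        written.append(p)
    if concordance_table is not None:
        p = out_dir / "concordance.tsv"
        concordance_table.to_csv(p, sep="\t", index=False, na_rep="NA")
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# Packaged example tables

def _data_path(name: str):
    return resources.files("sweepscan.data").joinpath(name)


def load_sle_regions() -> list[RegionSpec]:
    """The packaged 74-region SLE candidate list (hg18 Mb coordinates)."""
    with resources.as_file(_data_path("sle_regions.tsv")) as p:
        return read_regions(p)


def _genes(name: str) -> frozenset:
    return frozenset(g.strip().upper() for g in name.split(","))


def _attach_to_region_list(evidence: list[RegionEvidence],
                           regions: list[RegionSpec]) -> list[RegionEvidence]:
    """Join evidence rows onto the full region list by shared gene name.

    Regions without an evidence row get empty evidence (no signal).
    Printed evidence tables sometimes name only the lead gene of a
    multi-gene region, so the join matches on gene-set intersection.
    """
    out = []
    by_genes = {id(ev): _genes(ev.region.name) for ev in evidence}
    used = set()
    for region in regions:
        rg = _genes(region.name)
        hit = None
        for ev in evidence:
            if by_genes[id(ev)] & rg:
                hit = ev
                break
        if hit is not None:
            used.add(id(hit))
            out.append(hit)
        else:
            out.append(RegionEvidence(region=region))
    for ev in evidence:
        if id(ev) not in used:
            out.append(ev)
    return out


def load_hapmap_evidence(join_regions: bool = True) -> list[RegionEvidence]:
    """Per-region evidence transcribed from the HapMap-based scan browser."""
    with resources.as_file(_data_path("hapmap_region_evidence.tsv")) as p:
        df = pd.read_csv(p, sep="\t", na_values=["NA"], dtype={"chrom": str})
    out = []
    for _, row in df.iterrows():
        ev = RegionEvidence(region=RegionSpec(str(row["region"]), str(row["chrom"]),
                                              float(row["center_mb"])))
        for stat in ("ihs", "tajd", "fst"):
            if pd.notna(row[f"neglogq_{stat}"]):
                pop = row[f"neglogq_{stat}_pop"]
                ev.max_neglogq[stat] = (float(row[f"neglogq_{stat}"]),
                                        "" if pd.isna(pop) else str(pop))
        if pd.notna(row["top1_fst_value"]):
            pair = row["top1_fst_pair"]
            ev.top1pct_fst_hits.append(
                (".", float(row["top1_fst_value"]),
                 "" if pd.isna(pair) else str(pair)))
        if pd.notna(row["min_gene_p"]):
            ev.min_gene_p = (float(row["min_gene_p"]), str(row["min_gene_p_pop"]))
        out.append(ev)
    if join_regions:
        out = _attach_to_region_list(out, load_sle_regions())
    return out


def load_hgdp_evidence(join_regions: bool = True) -> list[RegionEvidence]:
    """Per-region maxima transcribed from the HGDP-based scan browser."""
    with resources.as_file(_data_path("hgdp_region_evidence.tsv")) as p:
        df = pd.read_csv(p, sep="\t", na_values=["NA"], dtype={"chrom": str})
    out = []
    for _, row in df.iterrows():
        ev = RegionEvidence(region=RegionSpec(str(row["region"]), str(row["chrom"]),
                                              float(row["center_mb"])))
        for stat in ("fst", "ihs", "xpehh"):
            if pd.notna(row[f"neglogp_{stat}"]):
                pop = row[f"neglogp_{stat}_pop"]
                ev.max_neglogp[stat] = (float(row[f"neglogp_{stat}"]),
                                        "" if pd.isna(pop) else str(pop))
        out.append(ev)
    if join_regions:
        out = _attach_to_region_list(out, load_sle_regions())
    return out
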