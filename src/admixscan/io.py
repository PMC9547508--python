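"""Readers and writers for the pipeline's on-disk formats.

Formats: phased VCF 4.2 (GT with "|", INFO/AA carrying the ancestral
allele), HapMap-format genetic-map text (``position COMBINED_rate(cM/Mb)
Genetic_Map(cM)``), population TSV (sample_id, population), and ancestry
tract TSV (haplotype_id, chrom, start_bp, end_bp, label) with half-open,
0-based intervals.  VCF positions are 1-based throughout.

Reading VCF goes through cyvcf2; writing emits plain text so simulated
panels stay text-only and round-trip bit-exactly through the reader.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panel import GeneticMap, HaplotypePanel, PopulationMap
from .ancestry import AncestryMatrix

logger = logging.getLogger("admixscan")

__all__ = [
    "read_phased_vcf",
    "write_phased_vcf",
    "read_genetic_map",
    "write_genetic_map",
    "read_population_map",
    "write_population_map",
    "read_ancestry_tracts",
    "write_ancestry_tracts",
    "ancestry_matrix_from_tracts",
]


def read_phased_vcf(
    path: str | Path,
    region: str | None = None,
    polarization: dict[int, str] | None = None,
) -> HaplotypePanel:
    """Load biallelic phased SNPs from a VCF into a HaplotypePanel.

    The ancestral allele comes from INFO/AA or, failing that, a
    ``polarization`` table mapping position to ancestral base.  Records that
    are multiallelic, non-SNP, unphased, or contain missing genotypes are
    skipped with counted warnings.  Sites whose ancestral allele is absent
    or matches neither REF nor ALT are kept, coded against REF, and flagged
    unpolarized.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path} has no sample/GT columns")
    skipped = {"multiallelic_or_not_snp": 0, "unphased_or_missing": 0}
    cols: list[np.ndarray] = []
    meta: list[tuple] = []
    it = vcf(region) if region else vcf
    for rec in it:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped["multiallelic_or_not_snp"] += 1
            continue
        gt = np.asarray(rec.genotype.array())
        alleles = gt[:, :2]
        phased = gt[:, 2]
        if (alleles < 0).any() or not phased.all():
            skipped["unphased_or_missing"] += 1
            continue
        aa = rec.INFO.get("AA")
        if aa is None and polarization is not None:
            aa = polarization.get(rec.POS)
        aa = aa.upper() if isinstance(aa, str) else None
        polarized = aa in (rec.REF, rec.ALT[0])
        hap = alleles.reshape(-1).astype(np.uint8)  # ALT-coded
        if polarized and aa == rec.ALT[0]:
            hap = 1 - hap  # ancestral is ALT: flip so 1 = derived
        meta.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0], aa, polarized))
        cols.append(hap)
    for reason, n in skipped.items():
        if n:
            logger.warning("%s: skipped %d record(s): %s", path.name, n, reason)
    if not cols:
        raise ValueError(f"no usable biallelic phased SNPs in {path}")
    sites = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt", "aa", "polarized"])
    return HaplotypePanel(
        haplotypes=np.column_stack(cols),
        sites=sites,
        sample_ids=samples,
    )


def write_phased_vcf(panel: HaplotypePanel, path: str | Path) -> Path:
    """Emit a panel as an uncompressed phased VCF 4.2 with INFO/AA."""
    path = Path(path)
    hap = panel.haplotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = panel.sites["chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        for m, row in enumerate(panel.sites.itertuples(index=False)):
            col = hap[:, m]
            if row.polarized and row.aa == row.alt:
                col = 1 - col  # stored 1 = derived; VCF wants ALT coding
            gts = "\t".join(f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(len(panel.sample_ids)))
            info = f"AA={row.aa}" if row.aa else "."
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )
    return path


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Parse a HapMap-format genetic map (whitespace-delimited, with header)."""
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+")
    if df.shape[0] < 2:
        raise ValueError(f"{path}: genetic map needs at least 2 data lines")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected columns position, rate(cM/Mb), cumulative cM")
    pos = df.iloc[:, 0].to_numpy(dtype=np.int64)
    rate = df.iloc[:, 1].to_numpy(dtype=float)
    cum = df.iloc[:, 2].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(cum) < 0)[0]
    if bad.size:
        raise ValueError(
            f"{path}: cumulative cM decreases at line {bad[0] + 3} (position {pos[bad[0] + 1]})"
        )
    return GeneticMap(pos, rate, cum)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> Path:
    path = Path(path)
    gmap.to_frame().to_csv(path, sep=" ", index=False)
    return path


def read_population_map(path: str | Path) -> PopulationMap:
    """TSV with columns sample_id, population (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 0] in ("sample_id", "sample"):
        df = df.iloc[1:]
    return PopulationMap(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_population_map(pops: PopulationMap, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for s, p in pops.sample_to_pop.items():
            fh.write(f"{s}\t{p}\n")
    return path


def write_ancestry_tracts(tracts: pd.DataFrame, path: str | Path) -> Path:
    """Tract TSV: haplotype_id, chrom, start_bp, end_bp, label (half-open, 0-based)."""
    path = Path(path)
    cols = ["haplotype_id", "chrom", "start_bp", "end_bp", "label"]
    tracts[cols].to_csv(path, sep="\t", index=False)
    return path


def read_ancestry_tracts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"haplotype_id", "chrom", "start_bp", "end_bp", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: tract table lacks columns {sorted(missing)}")
    return df


def ancestry_matrix_from_tracts(
    tracts: pd.DataFrame,
    positions_bp: np.ndarray,
    genetic_pos_cM: np.ndarray | None = None,
) -> AncestryMatrix:
    """Rasterize half-open tract intervals onto site positions.

    A site at 1-based position p falls in tract [start_bp, end_bp) when
    start_bp <= p - 1 < end_bp (tracts use 0-based coordinates).
    """
    positions_bp = np.asarray(positions_bp, dtype=np.int64)
    hap_ids = list(dict.fromkeys(tracts["haplotype_id"]))
    chrom = str(tracts["chrom"].iloc[0])
    labels = np.zeros((len(hap_ids), positions_bp.size), dtype=np.uint8)
    p0 = positions_bp - 1
    for h, hid in enumerate(hap_ids):
        sub = tracts[tracts["haplotype_id"] == hid]
        covered = np.zeros(positions_bp.size, dtype=bool)
        for row in sub.itertuples(index=False):
            inside = (p0 >= row.start_bp) & (p0 < row.end_bp)
            labels[h, inside] = row.label
            covered |= inside
        if not covered.all():
            raise ValueError(f"haplotype {hid}: tracts do not cover every site")
    return AncestryMatrix(hap_ids, chrom, positions_bp, labels, genetic_pos_cM)
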