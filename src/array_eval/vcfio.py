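"""VCF and TSV I/O.

Reading goes through cyvcf2 (``gts012`` mode, so genotype codes are
0 hom-ref / 1 het / 2 hom-alt / 3 unknown). Writing targets plain
uncompressed VCF 4.2 text, which every downstream tool accepts and keeps
generated fixtures human-readable.

Panel readers decompose multi-allelic sites into one biallelic record per
alternate allele and skip indels — LD-based coverage is defined over SNVs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .coverage import HaplotypePanel
from .imputation_eval import GenotypeTable, MISSING

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def read_ancestry_map(path: str) -> dict[str, str]:
    """Read a sample-to-ancestry TSV (columns ``sample, ancestry``)."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"].astype(str), df["ancestry"].astype(str)))


def write_ancestry_map(panel: HaplotypePanel, path: str) -> None:
    pd.DataFrame({"sample": panel.samples, "ancestry": panel.sample_ancestry}).to_csv(
        path, sep="\t", index=False
    )


def write_panel_vcf(panel: HaplotypePanel, path: str) -> None:
    """Write phased panel haplotypes as VCF (GT only, ``a|b``)."""
    h = panel.haplotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(panel.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        for j, row in panel.variants.iterrows():
            gts = "\t".join(
                f"{h[2 * i, j]}|{h[2 * i + 1, j]}" for i in range(panel.n_samples)
            )
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_panel_vcf(path: str, ancestry: dict[str, str]) -> HaplotypePanel:
    """Read a phased VCF into a haplotype panel.

    ``ancestry`` maps sample name to ancestry label; samples absent from the
    map get label ``unknown``. Multi-allelic SNV sites are decomposed to one
    indicator column per alternate allele; indel alleles are skipped.
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    rows: list[dict] = []
    cols: list[np.ndarray] = []
    for v in vcf:
        if len(v.REF) != 1:
            continue
        gt = np.asarray(v.genotypes, dtype=int)  # (n, 3): a0, a1, phased
        allele_mat = gt[:, :2].reshape(-1)  # haplotype-major: s0h0, s0h1, s1h0...
        for k, alt in enumerate(v.ALT, start=1):
            if len(alt) != 1:
                continue
            rows.append(dict(chrom=str(v.CHROM), pos=int(v.POS), ref=v.REF, alt=alt))
            cols.append((allele_mat == k).astype(np.uint8))
    hap = np.column_stack(cols) if cols else np.zeros((2 * len(samples), 0), dtype=np.uint8)
    return HaplotypePanel(
        variants=pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"]),
        haplotypes=hap,
        samples=samples,
        sample_ancestry=np.array([ancestry.get(s, "unknown") for s in samples], dtype=object),
    )


def write_genotype_vcf(table: GenotypeTable, path: str, info_fields: bool = False) -> None:
    """Write a genotype table as unphased VCF; INFO carries R2/AF when present."""
    has_info = info_fields and "r2" in table.variants.columns
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_info:
            fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">\n')
            fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        for chrom in pd.unique(table.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for i, row in table.variants.iterrows():
            info = "."
            if has_info:
                info = f"R2={row.r2:.6g};AF={row.maf:.6g}"
            gts = "\t".join(_GT_STR[int(g)] for g in table.gt[i])
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t{info}\tGT\t{gts}\n")


def read_genotype_vcf(path: str) -> GenotypeTable:
    """Read a VCF with GT (and optional INFO R2/AF) into a genotype table."""
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    rows: list[dict] = []
    gts: list[np.ndarray] = []
    for v in vcf:
        rec = dict(chrom=str(v.CHROM), pos=int(v.POS), ref=v.REF,
                   alt=v.ALT[0] if v.ALT else "")
        r2 = v.INFO.get("R2")
        af = v.INFO.get("AF")
        if r2 is not None:
            rec["r2"] = float(r2)
        if af is not None:
            af = float(af)
            rec["maf"] = min(af, 1.0 - af)
        rows.append(rec)
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        gts.append(g)
    gt = np.vstack(gts) if gts else np.zeros((0, len(samples)), dtype=np.int8)
    return GenotypeTable(variants=pd.DataFrame(rows), samples=samples, gt=gt)
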