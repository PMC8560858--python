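"""Gene-category content metrics.

Covers the clinically oriented comparisons: variant counts in gene sets
(e.g. the 59 ACMG actionable genes, 388 pharmacogenes), proxy-deleterious
counts (CADD phred > 20, the top ~1% most damaging), star-allele and HLA
identifiability from tag-SNV definitions, mtDNA locus tallies over
overlapping functional loci, and SNV density per gene CDS and per fixed
genomic window.

A star (*) allele is identifiable on an array only if its ENTIRE defining
tag-SNV haplotype is assayed (all-or-nothing); in imputed mode a tag SNV may
instead be covered by imputation at R^2 > 0.8. HLA tag sets are
ancestry-specific, so HLA percentages are computed per ancestry.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .imputation_eval import ImputedCallset
from .manifests import ArrayManifest, normalize_chrom

logger = logging.getLogger(__name__)

DEFAULT_CADD_MIN = 20.0
DEFAULT_R2_MIN = 0.8
MT_LENGTH = 16_569

GENE_CATEGORIES = ("acmg", "pharmacogene", "hla", "other")


@dataclass
class GeneRegion:
    """One gene's merged CDS intervals (1-based, ends inclusive)."""

    gene: str
    chrom: str
    intervals: list[tuple[int, int]]
    category: str = "other"

    def __post_init__(self) -> None:
        self.intervals = _merge_intervals(self.intervals)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    if any(s > e or s < 1 for s, e in ivs):
        raise ValueError("intervals must satisfy 1 <= start <= end")
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def read_gene_regions(path: str) -> list[GeneRegion]:
    """Read a gene/CDS interval TSV: gene, chrom, start, end[, category]."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for (gene, chrom), grp in df.groupby(["gene", "chrom"], sort=True):
        cat = grp["category"].iloc[0] if "category" in grp.columns else "other"
        out.append(
            GeneRegion(
                gene=str(gene),
                chrom=normalize_chrom(chrom),
                intervals=list(zip(grp["start"].astype(int), grp["end"].astype(int))),
                category=str(cat),
            )
        )
    return out


def _gene_trees(genes: list[GeneRegion]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.intervals:
            tree.addi(s, e + 1, g.gene)  # intervaltree is half-open
    return trees


def count_gene_variants(manifest: ArrayManifest, genes: list[GeneRegion]) -> pd.Series:
    """Per-gene count of array variants whose position falls in the gene's CDS.

    Membership is positional only; a variant inside two overlapping genes
    counts toward both.
    """
    trees = _gene_trees(genes)
    counts = pd.Series(0, index=[g.gene for g in genes], dtype=int)
    for chrom, pos in zip(manifest.df["chrom"], manifest.df["pos"].astype(int)):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree.at(pos):
            counts[iv.data] += 1
    return counts


@dataclass
class ProxyDeleteriousResult:
    """Per-gene counts of high-CADD variants plus distribution summaries."""

    per_gene: pd.Series
    total: int  # sum over genes (a variant in overlapping genes counts twice)
    distinct_total: int  # distinct qualifying variants
    median: float
    iqr: tuple[float, float]


def count_proxy_deleterious(
    manifest: ArrayManifest,
    genes: list[GeneRegion],
    cadd: pd.DataFrame,
    threshold: float = DEFAULT_CADD_MIN,
) -> ProxyDeleteriousResult:
    """Count array variants with CADD phred strictly above ``threshold`` per gene.

    ``cadd`` is keyed by full allele identity (chrom, pos, ref, alt ->
    cadd_phred); a score exactly at the threshold does not qualify. The
    median and IQR are taken across the whole gene list, zero-count genes
    included.
    """
    scores = {
        (normalize_chrom(c), int(p), r, a): float(s)
        for c, p, r, a, s in zip(
            cadd["chrom"], cadd["pos"], cadd["ref"], cadd["alt"], cadd["cadd_phred"]
        )
    }
    df = manifest.df
    qual = [
        scores.get((c, int(p), r, a), -np.inf) > threshold
        for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    ]
    sub = ArrayManifest(manifest.name, df.loc[qual], manifest.genome_build)
    per_gene = count_gene_variants(sub, genes)
    # distinct variants falling in >= 1 gene
    trees = _gene_trees(genes)
    distinct = sum(
        1
        for c, p in zip(sub.df["chrom"], sub.df["pos"].astype(int))
        if trees.get(c) is not None and trees[c].overlaps_point(p)
    )
    q1, med, q3 = np.percentile(per_gene.to_numpy(), [25, 50, 75])
    return ProxyDeleteriousResult(
        per_gene=per_gene,
        total=int(per_gene.sum()),
        distinct_total=int(distinct),
        median=float(med),
        iqr=(float(q1), float(q3)),
    )


class Callability(enum.Enum):
    CALLABLE = "callable"
    NOT_CALLABLE = "not_callable"
    NOT_EVALUABLE = "not_evaluable"


@dataclass
class StarAllele:
    """A named pharmacogene/HLA haplotype defined by a set of tag SNVs."""

    gene: str
    allele: str
    tag_snvs: list[tuple[str, int, str, str]]
    ancestry: str = "all"
    cnv_based: bool = False  # whole-gene deletion/duplication alleles


def read_star_alleles(path: str) -> list[StarAllele]:
    """Read a star-allele definition TSV: gene, allele, ancestry, chrom, pos, ref, alt."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for (gene, allele, anc), grp in df.groupby(["gene", "allele", "ancestry"], sort=True):
        tags = [
            (normalize_chrom(c), int(p), str(r), str(a))
            for c, p, r, a in zip(grp["chrom"], grp["pos"], grp["ref"], grp["alt"])
            if not pd.isna(p)
        ]
        out.append(StarAllele(gene=str(gene), allele=str(allele), tag_snvs=tags,
                              ancestry=str(anc)))
    return out


def star_allele_callable(
    allele: StarAllele,
    manifest: ArrayManifest,
    imputed: ImputedCallset | None = None,
    r2_min: float = DEFAULT_R2_MIN,
    position_only: bool = False,
) -> Callability:
    """All-or-nothing identifiability of one star allele.

    Array mode (``imputed`` is None): callable iff EVERY tag SNV is on the
    manifest, matching position and alleles (position-only matching behind
    the ``position_only`` flag). Imputed mode: a tag SNV may instead be
    present in the imputed callset with R^2 strictly above ``r2_min``.
    Alleles with no tag SNVs, or defined by CNVs, are not evaluable.
    """
    if allele.cnv_based or not allele.tag_snvs:
        return Callability.NOT_EVALUABLE
    if position_only:
        on_array = manifest.positions
        keys = [(c, p) for c, p, _, _ in allele.tag_snvs]
    else:
        on_array = manifest.allele_keys
        keys = list(allele.tag_snvs)
    imp_ok: set = set()
    if imputed is not None:
        v = imputed.variants
        hi = v["r2"].to_numpy() > r2_min
        if position_only:
            imp_ok = set(zip(v["chrom"][hi], v["pos"][hi].astype(int)))
        else:
            imp_ok = set(zip(v["chrom"][hi], v["pos"][hi].astype(int), v["ref"][hi], v["alt"][hi]))
    ok = all(k in on_array or k in imp_ok for k in keys)
    return Callability.CALLABLE if ok else Callability.NOT_CALLABLE


def percent_star_alleles(
    gene: str,
    alleles: list[StarAllele],
    manifest: ArrayManifest,
    imputed: ImputedCallset | None = None,
    r2_min: float = DEFAULT_R2_MIN,
    ancestry: str | None = None,
) -> float | None:
    """Percentage of a gene's evaluable star alleles that are callable.

    Returns None when the gene has no evaluable allele (undefined).
    """
    pool = [a for a in alleles if a.gene == gene
            and (ancestry is None or a.ancestry == ancestry)]
    statuses = [star_allele_callable(a, manifest, imputed, r2_min) for a in pool]
    evaluable = [s for s in statuses if s is not Callability.NOT_EVALUABLE]
    if not evaluable:
        return None
    n_call = sum(s is Callability.CALLABLE for s in evaluable)
    return 100.0 * n_call / len(evaluable)


@dataclass
class HlaCoverage:
    """Gene x ancestry star-allele percentages with per-gene mean and SD."""

    table: pd.DataFrame  # genes x ancestries, NaN where undefined
    mean_sd: pd.DataFrame  # per gene: mean, sd across ancestries


def hla_percent_by_ancestry(
    genes: list[str],
    alleles: list[StarAllele],
    manifest: ArrayManifest,
    imputed: ImputedCallset | None = None,
    r2_min: float = DEFAULT_R2_MIN,
    ancestries: tuple[str, ...] = ("EUR", "ASN", "AFR"),
) -> HlaCoverage:
    """Ancestry-stratified HLA star-allele identifiability.

    Tag-SNV sets differ between ancestries, so each cell applies the
    all-or-nothing rule to that ancestry's definitions. Cells with no
    defined alleles are NaN and omitted from the per-gene mean/SD
    (population SD across ancestries, matching an error-bar summary).
    """
    rows = {}
    for gene in genes:
        row = {}
        for anc in ancestries:
            pct = percent_star_alleles(gene, alleles, manifest, imputed, r2_min, ancestry=anc)
            if pct is None:
                logger.warning("no evaluable %s alleles for ancestry %s", gene, anc)
                row[anc] = np.nan
            else:
                row[anc] = pct
        rows[gene] = row
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(ancestries))
    mean_sd = pd.DataFrame(
        {"mean": table.mean(axis=1, skipna=True),
         "sd": table.std(axis=1, ddof=0, skipna=True)}
    )
    return HlaCoverage(table=table, mean_sd=mean_sd)


@dataclass
class MtLocus:
    """A mitochondrial functional locus; loci may overlap one another."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end <= MT_LENGTH:
            raise ValueError(f"mtDNA locus {self.name}: bad bounds {self.start}-{self.end}")


def read_mt_loci(path: str) -> list[MtLocus]:
    """Read an mtDNA locus TSV: name, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    return [MtLocus(str(n), int(s), int(e))
            for n, s, e in zip(df["name"], df["start"], df["end"])]


@dataclass
class MtTally:
    per_locus: pd.Series
    total: int  # distinct MT variants, counted once however many loci overlap


def mtdna_tally(manifest: ArrayManifest, loci: list[MtLocus]) -> MtTally:
    """Count array mtDNA variants per functional locus and in total.

    Loci overlap, so a variant increments every locus containing it; the
    total counts each distinct MT variant once.
    """
    mt = manifest.df.loc[manifest.df["chrom"] == "MT"]
    positions = mt["pos"].astype(int).to_numpy()
    per_locus = pd.Series(
        {loc.name: int(((positions >= loc.start) & (positions <= loc.end)).sum())
         for loc in loci},
        dtype=int,
    )
    return MtTally(per_locus=per_locus, total=len(mt))


def cds_density(manifest: ArrayManifest, genes: list[GeneRegion]) -> pd.DataFrame:
    """Mean inter-SNV distance per gene: CDS length / (SNVs in CDS + 1).

    Only probes of class ``snv`` count. A zero-length gene is an error.
    Returns a frame with cds_length, n_snvs and mean_distance per gene.
    """
    snv_manifest = ArrayManifest(
        manifest.name,
        manifest.df.loc[manifest.df["probe_class"] == "snv"],
        manifest.genome_build,
    ) if (manifest.df["probe_class"] != "snv").any() else manifest
    counts = count_gene_variants(snv_manifest, genes)
    rows = []
    for g in genes:
        if g.cds_length <= 0:
            raise ValueError(f"gene {g.gene} has zero-length CDS")
        n = int(counts[g.gene])
        rows.append(dict(gene=g.gene, cds_length=g.cds_length, n_snvs=n,
                         mean_distance=g.cds_length / (n + 1)))
    return pd.DataFrame(rows).set_index("gene")


@dataclass
class WindowDensity:
    window_bp: int
    per_window: pd.DataFrame  # chrom, window_start, count
    mean: float
    sd: float  # population SD over all windows genome-wide


def window_density(
    manifest: ArrayManifest,
    window_bp: int,
    chrom_lengths: dict[str, int],
) -> WindowDensity:
    """SNV counts in fixed non-overlapping windows anchored at position 1.

    Every chromosome in ``chrom_lengths`` contributes ceil(len/window)
    windows (including empty ones); the mean and SD are over all windows.
    A manifest variant on a chromosome not listed, or beyond its stated
    length, is an error.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    frames = []
    df = manifest.df
    for chrom, pos in zip(df["chrom"], df["pos"].astype(int)):
        if chrom not in chrom_lengths:
            raise ValueError(f"variant on chromosome {chrom} without a stated length")
        if pos > chrom_lengths[chrom]:
            raise ValueError(f"variant {chrom}:{pos} beyond chromosome length")
    counts_all = []
    for chrom in sorted(chrom_lengths):
        n_win = int(np.ceil(chrom_lengths[chrom] / window_bp))
        sel = df.loc[df["chrom"] == chrom, "pos"].astype(int).to_numpy()
        counts = np.bincount((sel - 1) // window_bp, minlength=n_win)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "window_start": np.arange(n_win, dtype=int) * window_bp + 1,
            "count": counts,
        }))
        counts_all.append(counts)
    per_window = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "window_start", "count"])
    allc = np.concatenate(counts_all) if counts_all else np.array([0])
    return WindowDensity(window_bp=window_bp, per_window=per_window,
                         mean=float(allc.mean()), sd=float(allc.std(ddof=0)))
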