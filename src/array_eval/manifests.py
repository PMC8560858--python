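"""Array manifest handling.

A genotyping-array manifest lists every probe the array assays: genomic
position, alleles and probe type. Vendors ship them in slightly different
dialects; this module reads BED-like and CSV manifests into a harmonized
:class:`ArrayManifest`, classifies content (autosomal / X / Y / mtDNA SNVs,
CNV intensity-only probes, exonic and splice-site variants) and computes
position-based overlap between arrays.

Coordinates are 1-based internally (VCF convention). BED input, which is
0-based half-open, is converted on read and back on write. Chromosome labels
are normalized by stripping a leading ``chr`` and mapping ``M`` to ``MT``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ALLOWED_CHROMS: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")
AUTOSOMES: frozenset[str] = frozenset(str(i) for i in range(1, 23))

PROBE_CLASSES = ("snv", "indel", "cnv_intensity")
FUNCTIONAL_CLASSES = ("exonic", "splice_site", "other")

#: columns every manifest frame carries, in order
MANIFEST_COLUMNS = ["chrom", "pos", "ref", "alt", "probe_class", "functional"]


class ManifestError(ValueError):
    """Raised for unparseable manifest content."""


def normalize_chrom(label: str) -> str:
    """Normalize a chromosome label to the fixed allowed set.

    Strips a leading ``chr`` (any case) and maps ``M`` to ``MT``. Raises
    :class:`ManifestError` for labels outside 1-22, X, Y, MT.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    if s == "M":
        s = "MT"
    if s not in ALLOWED_CHROMS:
        raise ManifestError(f"unknown chromosome label: {label!r}")
    return s


def _infer_probe_class(ref: str, alt: str) -> str:
    if not ref and not alt:
        return "cnv_intensity"
    if len(ref) != 1 or len(alt) != 1 or "-" in (ref, alt):
        return "indel"
    return "snv"


@dataclass
class ArrayManifest:
    """One array's content: a frame of variants plus identifying metadata.

    ``df`` has columns ``chrom, pos, ref, alt, probe_class, functional``.
    ``ref``/``alt`` are empty strings for intensity-only (CNV) probes.
    No two rows share (chrom, pos, ref, alt).
    """

    name: str
    df: pd.DataFrame
    genome_build: str = "hg19"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("manifest name must be non-empty")
        missing = [c for c in MANIFEST_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"manifest frame missing columns: {missing}")
        self.df = self.df[MANIFEST_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def positions(self) -> set[tuple[str, int]]:
        """Distinct (chrom, pos) pairs on the array."""
        return set(zip(self.df["chrom"], self.df["pos"].astype(int)))

    @property
    def allele_keys(self) -> set[tuple[str, int, str, str]]:
        """Distinct (chrom, pos, ref, alt) keys on the array."""
        return set(
            zip(self.df["chrom"], self.df["pos"].astype(int), self.df["ref"], self.df["alt"])
        )


@dataclass(frozen=True)
class ContentSummary:
    """Table-1-style content counts for one array."""

    name: str
    total: int
    autosomal: int
    x: int
    y: int
    exonic: int
    splice_site: int
    cnv: int
    mt: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__]).set_index("name")


@dataclass
class OverlapMatrix:
    """Pairwise shared-position counts between arrays.

    Symmetric; the diagonal is each array's distinct-position count.
    """

    arrays: list[str]
    counts: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not np.array_equal(self.counts.values, self.counts.values.T):
            raise ValueError("overlap matrix must be symmetric")


def _build_frame(rows: list[dict], path: str) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    n_before = len(df)
    df = df.drop_duplicates(subset=["chrom", "pos", "ref", "alt"], keep="first")
    n_dup = n_before - len(df)
    if n_dup:
        logger.warning("%s: collapsed %d duplicate manifest row(s)", path, n_dup)
    return df.reset_index(drop=True)


def read_manifest(path: str, name: str, format: str = "bed") -> ArrayManifest:
    """Read an array manifest from BED (0-based half-open) or CSV (1-based).

    BED columns: chrom, start, end, then optionally id, ref, alt,
    probe_class, functional. CSV needs a header with at least ``chrom,pos``;
    ``ref, alt, probe_class, functional`` are honoured when present.

    Duplicate (chrom, pos, ref, alt) records are collapsed to the first
    occurrence with a logged warning. Unknown chromosome labels and
    unparseable lines raise :class:`ManifestError` naming the line number.
    """
    if format not in ("bed", "csv"):
        raise ValueError(f"unknown manifest format: {format!r}")
    rows: list[dict] = []
    with open(path, newline="") as fh:
        if format == "bed":
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ManifestError(f"{path}:{lineno}: expected >=3 BED fields")
                try:
                    chrom = normalize_chrom(fields[0])
                    start = int(fields[1])
                except (ManifestError, ValueError) as exc:
                    raise ManifestError(f"{path}:{lineno}: {exc}") from exc
                ref = fields[4] if len(fields) > 4 else ""
                alt = fields[5] if len(fields) > 5 else ""
                ref = "" if ref == "." else ref
                alt = "" if alt == "." else alt
                probe = fields[6] if len(fields) > 6 and fields[6] else _infer_probe_class(ref, alt)
                func = fields[7] if len(fields) > 7 and fields[7] else "other"
                rows.append(
                    dict(chrom=chrom, pos=start + 1, ref=ref, alt=alt,
                         probe_class=probe, functional=func)
                )
        else:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "chrom" not in reader.fieldnames \
                    or "pos" not in reader.fieldnames:
                raise ManifestError(f"{path}: CSV manifest needs a header with chrom,pos")
            for lineno, rec in enumerate(reader, start=2):
                try:
                    chrom = normalize_chrom(rec["chrom"])
                    pos = int(rec["pos"])
                except (ManifestError, ValueError, TypeError) as exc:
                    raise ManifestError(f"{path}:{lineno}: {exc}") from exc
                ref = (rec.get("ref") or "").strip()
                alt = (rec.get("alt") or "").strip()
                ref = "" if ref == "." else ref
                alt = "" if alt == "." else alt
                probe = rec.get("probe_class") or _infer_probe_class(ref, alt)
                func = rec.get("functional") or "other"
                rows.append(
                    dict(chrom=chrom, pos=pos, ref=ref, alt=alt,
                         probe_class=probe, functional=func)
                )
    df = _build_frame(rows, path)
    bad = ~df["probe_class"].isin(PROBE_CLASSES)
    if bad.any():
        raise ManifestError(
            f"{path}: unknown probe_class value(s): {sorted(df.loc[bad, 'probe_class'].unique())}"
        )
    if (df["pos"] < 1).any():
        raise ManifestError(f"{path}: positions must be >= 1")
    return ArrayManifest(name=name, df=df)


def write_manifest(manifest: ArrayManifest, path: str, format: str = "bed") -> None:
    """Write a manifest back out; BED converts to 0-based half-open."""
    df = manifest.df
    if format == "bed":
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["pos"].astype(int) - 1,
                "end": df["pos"].astype(int),
                "id": [f"{manifest.name}_{i}" for i in range(len(df))],
                "ref": df["ref"].replace("", "."),
                "alt": df["alt"].replace("", "."),
                "probe_class": df["probe_class"],
                "functional": df["functional"],
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)
    elif format == "csv":
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown manifest format: {format!r}")


def summarize_content(manifest: ArrayManifest) -> ContentSummary:
    """Partition array content by chromosome class and functional annotation.

    CNV intensity-only probes are counted separately regardless of
    chromosome; mtDNA variants likewise form their own class, so
    autosomal + x + y + mt + cnv == total.
    """
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    df = manifest.df
    is_cnv = df["probe_class"] == "cnv_intensity"
    gt = df.loc[~is_cnv]
    return ContentSummary(
        name=manifest.name,
        total=len(df),
        autosomal=int(gt["chrom"].isin(AUTOSOMES).sum()),
        x=int((gt["chrom"] == "X").sum()),
        y=int((gt["chrom"] == "Y").sum()),
        exonic=int((df["functional"] == "exonic").sum()),
        splice_site=int((df["functional"] == "splice_site").sum()),
        cnv=int(is_cnv.sum()),
        mt=int((gt["chrom"] == "MT").sum()),
    )


def classify_functional(manifest: ArrayManifest, annotation: pd.DataFrame) -> ArrayManifest:
    """Attach functional classes from an annotation table.

    ``annotation`` maps (chrom, pos, ref, alt) to a functional class
    (columns ``chrom, pos, ref, alt, functional``). Variants without a
    matching key are classed ``other``.
    """
    df = manifest.df.copy()
    if len(annotation) == 0:
        df["functional"] = "other"
        return ArrayManifest(manifest.name, df, manifest.genome_build)
    ann = annotation.copy()
    ann["chrom"] = ann["chrom"].map(normalize_chrom)
    ann = ann.drop_duplicates(subset=["chrom", "pos", "ref", "alt"], keep="first")
    key = ["chrom", "pos", "ref", "alt"]
    merged = df.drop(columns="functional").merge(
        ann[key + ["functional"]], on=key, how="left"
    )
    merged["functional"] = merged["functional"].fillna("other")
    return ArrayManifest(manifest.name, merged, manifest.genome_build)


def overlap_matrix(manifests: list[ArrayManifest]) -> OverlapMatrix:
    """Count distinct (chrom, pos) shared by each pair of arrays.

    Alleles are ignored: two arrays overlap at a site if both assay any
    variant there. All manifests must share a genome build.
    """
    if not manifests:
        raise ValueError("need at least one manifest")
    builds = {m.genome_build for m in manifests}
    if len(builds) > 1:
        raise ValueError(f"mixed genome builds: {sorted(builds)}")
    names = [m.name for m in manifests]
    pos_sets = [m.positions for m in manifests]
    n = len(manifests)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        counts[i, i] = len(pos_sets[i])
        for j in range(i + 1, n):
            counts[i, j] = counts[j, i] = len(pos_sets[i] & pos_sets[j])
    return OverlapMatrix(arrays=names, counts=pd.DataFrame(counts, index=names, columns=names))
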