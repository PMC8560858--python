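"""Genome-wide coverage from phased haplotypes via LD tagging.

Genome-wide coverage of an array is the fraction of reference-panel SNVs it
captures, directly or through linkage disequilibrium. An off-array panel SNV
counts as captured when some array SNV within a physical window tags it at
r^2 above a threshold (0.8 by default, strict inequality). The coverage rate
is then

    CR = (L/(R - T) * (G - T) + T) / G

where L is the number of off-array panel SNVs tagged, R the panel SNV count
after MAF filtering, T the total number of variants on the array, and G an
assumed genome-wide SNV count (~19 million validated SNVs with MAF > 1%).

r^2 between two biallelic variants is the squared correlation of their
haplotype indicators: D^2 / (pA(1-pA) pB(1-pB)) with D = pAB - pA*pB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .manifests import ArrayManifest

DEFAULT_GENOME_SNVS = 19_000_000
DEFAULT_R2_MIN = 0.8
DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_MIN_MAF = 0.01


class MonomorphicVariantError(ValueError):
    """LD is undefined for a variant with a single allele in the subset."""


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes with per-sample ancestry labels.

    ``haplotypes`` is a (2n x m) 0/1 matrix; sample i owns rows 2i and
    2i + 1. ``variants`` has columns ``chrom, pos, ref, alt`` (extra columns
    are carried along untouched).
    """

    variants: pd.DataFrame
    haplotypes: np.ndarray = field(repr=False)
    samples: list[str]
    sample_ancestry: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.sample_ancestry = np.asarray(self.sample_ancestry, dtype=object)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[0] % 2 != 0:
            raise ValueError("haplotype count must be even (phased diploids)")
        if self.haplotypes.shape[0] != 2 * len(self.samples):
            raise ValueError("haplotype rows must equal 2 x samples")
        if len(self.sample_ancestry) != len(self.samples):
            raise ValueError("one ancestry label per sample required")
        if self.haplotypes.shape[1] != len(self.variants):
            raise ValueError("haplotype columns must equal variant count")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("haplotype entries must be 0/1")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def ancestries(self) -> list[str]:
        return sorted(set(self.sample_ancestry))

    @property
    def maf(self) -> np.ndarray:
        """Minor-allele frequency per variant over all haplotypes."""
        p = self.haplotypes.mean(axis=0)
        return np.minimum(p, 1.0 - p)

    def genotypes(self) -> np.ndarray:
        """Diploid allele-count genotypes (n_variants x n_samples) in {0,1,2}."""
        h = self.haplotypes.astype(np.int8)
        return (h[0::2] + h[1::2]).T


def filter_panel_by_maf(
    panel: HaplotypePanel, ancestry: str, min_maf: float = DEFAULT_MIN_MAF
) -> HaplotypePanel:
    """Restrict a panel to one ancestry and to variants with MAF >= min_maf.

    MAF is recomputed within the ancestry subset; the threshold is inclusive
    ("1% or higher"). Monomorphic variants (MAF 0) are always dropped for any
    positive threshold.
    """
    mask = panel.sample_ancestry == ancestry
    if not mask.any():
        raise ValueError(f"ancestry {ancestry!r} not present in panel")
    hap_mask = np.repeat(mask, 2)
    sub = panel.haplotypes[hap_mask]
    p = sub.mean(axis=0)
    keep = np.minimum(p, 1.0 - p) >= min_maf
    return HaplotypePanel(
        variants=panel.variants.loc[keep].reset_index(drop=True),
        haplotypes=sub[:, keep],
        samples=[s for s, m in zip(panel.samples, mask) if m],
        sample_ancestry=panel.sample_ancestry[mask],
    )


def ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Haplotype r^2 between two biallelic variants.

    ``a`` and ``b`` are equal-length 0/1 indicator vectors over the same
    haplotypes. Raises :class:`MonomorphicVariantError` if either variant is
    monomorphic (r^2 undefined; such variants are excluded from tagging).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise MonomorphicVariantError("monomorphic variant: r^2 undefined")
    d = (a * b).mean() - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def _pairwise_r2(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """r^2 between columns of A and columns of B (same haplotype rows).

    Monomorphic columns yield NaN rather than raising; callers mask them.
    """
    A = A.astype(float)
    B = B.astype(float)
    n = A.shape[0]
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    cov = Ac.T @ Bc / n
    va = (Ac * Ac).mean(axis=0)
    vb = (Bc * Bc).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = cov**2 / np.outer(va, vb)
    r2[va == 0, :] = np.nan
    r2[:, vb == 0] = np.nan
    return r2


@dataclass
class TagResult:
    """Off-array tagging outcome: L plus per-panel-variant audit flags."""

    L: int
    on_array: np.ndarray  # panel variant sits at an array position
    tagged: np.ndarray  # off-array panel variant tagged at r^2 > threshold


def count_tagged(
    array_positions: set[tuple[str, int]],
    panel: HaplotypePanel,
    r2_min: float = DEFAULT_R2_MIN,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> TagResult:
    """Count panel SNVs captured by the array through LD.

    A panel SNV not at an array position counts toward L when its r^2 with at
    least one on-array panel SNV within ``window_bp`` on the same chromosome
    strictly exceeds ``r2_min``. The panel should already be MAF-filtered.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    chroms = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy(dtype=np.int64)
    on_array = np.fromiter(
        ((c, int(p)) in array_positions for c, p in zip(chroms, pos)),
        dtype=bool,
        count=len(pos),
    )
    tagged = np.zeros(len(pos), dtype=bool)
    H = panel.haplotypes
    for chrom in pd.unique(chroms):
        cmask = chroms == chrom
        tag_idx = np.where(cmask & on_array)[0]
        off_idx = np.where(cmask & ~on_array)[0]
        if len(tag_idx) == 0 or len(off_idx) == 0:
            continue
        r2 = _pairwise_r2(H[:, off_idx], H[:, tag_idx])
        near = np.abs(pos[off_idx][:, None] - pos[tag_idx][None, :]) <= window_bp
        hit = np.nan_to_num(r2, nan=0.0) > r2_min
        tagged[off_idx] = (hit & near).any(axis=1)
    return TagResult(L=int(tagged.sum()), on_array=on_array, tagged=tagged)


@dataclass(frozen=True)
class CoverageResult:
    """Inputs and result of the coverage-rate equation."""

    L: int
    R: int
    T: int
    G: int
    cr: float


def coverage_rate(L: int, R: int, T: int, G: int = DEFAULT_GENOME_SNVS) -> CoverageResult:
    """Coverage rate CR = (L/(R-T) * (G-T) + T) / G.

    Requires R > T (the panel must extend beyond the array) and
    0 <= L <= R - T.
    """
    if T < 0 or L < 0:
        raise ValueError("counts must be non-negative")
    if R <= T:
        raise ValueError(f"R ({R}) must exceed T ({T})")
    if G < T:
        raise ValueError(f"G ({G}) must be >= T ({T})")
    if L > R - T:
        raise ValueError(f"L ({L}) cannot exceed R - T ({R - T})")
    cr = (L / (R - T) * (G - T) + T) / G
    return CoverageResult(L=L, R=R, T=T, G=G, cr=float(cr))


def coverage_by_ancestry(
    manifest: ArrayManifest,
    panel: HaplotypePanel,
    ancestries: list[str] | None = None,
    G: int = DEFAULT_GENOME_SNVS,
    r2_min: float = DEFAULT_R2_MIN,
    window_bp: int = DEFAULT_WINDOW_BP,
    min_maf: float = DEFAULT_MIN_MAF,
) -> dict[str, CoverageResult]:
    """Per-ancestry coverage: MAF-filter the panel, tag, apply the equation.

    T is the array's total variant count (its full content, whether or not a
    variant appears in the panel); R is the post-filter panel size; L the
    tagged off-array count.
    """
    if ancestries is None:
        ancestries = panel.ancestries
    positions = manifest.positions
    T = len(manifest)
    out: dict[str, CoverageResult] = {}
    for anc in ancestries:
        sub = filter_panel_by_maf(panel, anc, min_maf=min_maf)
        tag = count_tagged(positions, sub, r2_min=r2_min, window_bp=window_bp)
        out[anc] = coverage_rate(L=tag.L, R=sub.n_variants, T=T, G=G)
    return out


def taggability(
    panel: HaplotypePanel,
    r2_min: float = DEFAULT_R2_MIN,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> float:
    """Fraction of panel SNVs tagged by another panel SNV (self-pairs excluded).

    Measures how much of the panel is capturable by LD at all — an upper
    bound on what any array can reach through tagging.
    """
    chroms = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy(dtype=np.int64)
    n = len(pos)
    if n == 0:
        raise ValueError("empty panel")
    tagged = np.zeros(n, dtype=bool)
    H = panel.haplotypes
    for chrom in pd.unique(chroms):
        idx = np.where(chroms == chrom)[0]
        if len(idx) < 2:
            continue
        r2 = _pairwise_r2(H[:, idx], H[:, idx])
        np.fill_diagonal(r2, np.nan)
        near = np.abs(pos[idx][:, None] - pos[idx][None, :]) <= window_bp
        hit = np.nan_to_num(r2, nan=0.0) > r2_min
        tagged[idx] = (hit & near).any(axis=1)
    return float(tagged.mean())
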