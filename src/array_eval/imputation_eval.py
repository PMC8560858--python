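"""Imputation-quality binning, genotype QC and WES concordance.

Imputed callsets carry a per-variant quality R^2 (estimated squared
correlation between imputed dosage and true genotype, as reported by the
imputation service). Variants are stratified into four MAF bins
(<0.5%, 0.5-1%, 1-5%, >5%) and three quality bins (R^2 < 0.3 low,
0.3-0.8 medium, > 0.8 high).

Concordance against whole-exome sequencing of the same samples is computed
per individual over genotypes non-missing in both sets. For the ultra-rare
and rare MAF bins, homozygous-reference calls are first masked to missing in
BOTH sets, so the overabundance of reference alleles cannot inflate the
metric — only genotypes carrying a variant allele are compared.

Pre-imputation QC removes SNVs and samples with call rate < 97.5%, SNVs
failing Hardy-Weinberg equilibrium (exact conditional test, p < 1e-7,
autosomes), and samples with excess heterozygosity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .manifests import AUTOSOMES

MISSING = -1  # genotype codes: 0 hom_ref, 1 het, 2 hom_alt, -1 missing

DEFAULT_CALL_RATE_MIN = 0.975
DEFAULT_HWE_P_MIN = 1e-7
DEFAULT_HET_F_SD = 4.0


class MafBin(enum.Enum):
    ULTRA_RARE = "ultra_rare"  # (0, 0.005)
    RARE = "rare"  # [0.005, 0.01)
    LOW_FREQUENCY = "low_frequency"  # [0.01, 0.05)
    COMMON = "common"  # [0.05, 0.5]


class QualityBin(enum.Enum):
    LOW = "low"  # r2 < 0.3
    MEDIUM = "medium"  # 0.3 <= r2 <= 0.8
    HIGH = "high"  # r2 > 0.8


MASKED_BINS = (MafBin.ULTRA_RARE, MafBin.RARE)


@dataclass
class GenotypeTable:
    """Diploid genotype calls for a set of variants x samples.

    ``gt`` is an int8 matrix (n_variants x n_samples) coded 0/1/2 by
    alternate-allele count and -1 for missing. ``variants`` has columns
    ``chrom, pos, ref, alt`` plus optional ``r2`` and ``maf`` for imputed
    callsets.
    """

    variants: pd.DataFrame
    samples: list[str]
    gt: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.shape != (len(self.variants), len(self.samples)):
            raise ValueError("gt shape must be (n_variants, n_samples)")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(self.variants.copy(), list(self.samples), self.gt.copy())

    def variant_call_rate(self) -> np.ndarray:
        return (self.gt != MISSING).mean(axis=1)

    def sample_call_rate(self) -> np.ndarray:
        return (self.gt != MISSING).mean(axis=0)

    def variant_keys(self) -> pd.Index:
        v = self.variants
        return pd.Index(zip(v["chrom"], v["pos"].astype(int), v["ref"], v["alt"]))


#: an imputed callset is a genotype table whose variants carry r2 and maf
ImputedCallset = GenotypeTable


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of configurations no more probable
    than the observed one (conditional on allele counts; the standard exact
    conditional test).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_a = 2 * n_hom_alt + n_het  # minor-or-not, symmetry below handles either
    n_r = 2 * n - n_a
    rare = min(n_a, n_r)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    # log P(het = h | allele counts) up to the common normalizer
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def sample_inbreeding(table: GenotypeTable) -> np.ndarray:
    """Per-sample inbreeding coefficient F = 1 - observed het / expected het.

    Expected heterozygosity sums 2p(1-p) over the autosomal variants
    non-missing in the sample, with p the cohort alternate-allele frequency.
    Strongly negative F marks excess heterozygosity.
    """
    auto = table.variants["chrom"].isin(AUTOSOMES).to_numpy()
    gt = table.gt[auto]
    called = gt != MISSING
    with np.errstate(invalid="ignore"):
        p = np.where(
            called.sum(axis=1) > 0,
            np.where(gt == MISSING, 0, gt).sum(axis=1) / (2 * np.maximum(called.sum(axis=1), 1)),
            np.nan,
        )
    exp_het_per_variant = 2 * p * (1 - p)
    obs = ((gt == 1) & called).sum(axis=0)
    exp = np.where(called, exp_het_per_variant[:, None], 0.0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(exp > 0, 1.0 - obs / exp, np.nan)
    return f


def qc_filter(
    table: GenotypeTable,
    call_rate_min: float = DEFAULT_CALL_RATE_MIN,
    hwe_p_min: float = DEFAULT_HWE_P_MIN,
    het_f_sd: float = DEFAULT_HET_F_SD,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Standard pre-imputation QC.

    Removes, in order: SNVs with call rate below ``call_rate_min``; samples
    with call rate below ``call_rate_min``; autosomal SNVs with exact HWE
    p below ``hwe_p_min``; samples whose inbreeding coefficient lies more
    than ``het_f_sd`` SDs below the cohort mean (excess heterozygosity).
    Returns the filtered table and an exclusion report
    (columns ``kind, id, reason, value``).
    """
    if table.n_variants == 0 or table.n_samples == 0:
        raise ValueError("empty callset")
    records: list[dict] = []
    t = table.copy()

    vcr = t.variant_call_rate()
    drop_v = vcr < call_rate_min
    for i in np.where(drop_v)[0]:
        v = t.variants.iloc[i]
        records.append(dict(kind="variant", id=f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}",
                            reason="call_rate", value=float(vcr[i])))
    t = GenotypeTable(t.variants.loc[~drop_v], t.samples, t.gt[~drop_v])

    scr = t.sample_call_rate()
    drop_s = scr < call_rate_min
    for j in np.where(drop_s)[0]:
        records.append(dict(kind="sample", id=t.samples[j],
                            reason="call_rate", value=float(scr[j])))
    t = GenotypeTable(t.variants, [s for s, d in zip(t.samples, drop_s) if not d],
                      t.gt[:, ~drop_s])

    auto = t.variants["chrom"].isin(AUTOSOMES).to_numpy()
    drop_hwe = np.zeros(t.n_variants, dtype=bool)
    for i in np.where(auto)[0]:
        row = t.gt[i]
        counts = (int((row == 0).sum()), int((row == 1).sum()), int((row == 2).sum()))
        if sum(counts) == 0:
            continue
        p = hwe_exact_p(*counts)
        if p < hwe_p_min:
            drop_hwe[i] = True
            v = t.variants.iloc[i]
            records.append(dict(kind="variant", id=f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}",
                                reason="hwe", value=p))
    t = GenotypeTable(t.variants.loc[~drop_hwe], t.samples, t.gt[~drop_hwe])

    if t.n_samples >= 2 and t.n_variants > 0:
        f = sample_inbreeding(t)
        ok = ~np.isnan(f)
        if ok.sum() >= 2 and np.nanstd(f) > 0:
            cutoff = np.nanmean(f) - het_f_sd * np.nanstd(f)
            drop_het = ok & (f < cutoff)
            for j in np.where(drop_het)[0]:
                records.append(dict(kind="sample", id=t.samples[j],
                                    reason="excess_heterozygosity", value=float(f[j])))
            t = GenotypeTable(t.variants,
                              [s for s, d in zip(t.samples, drop_het) if not d],
                              t.gt[:, ~drop_het])

    report = pd.DataFrame(records, columns=["kind", "id", "reason", "value"])
    return t, report


def assign_maf_bin(maf: float) -> MafBin:
    """Map a MAF to its frequency bin.

    Bins are left-closed/right-open at 0.005, 0.01 and 0.05:
    (0, 0.005) ultra-rare, [0.005, 0.01) rare, [0.01, 0.05) low-frequency,
    [0.05, 0.5] common.
    """
    if not 0 < maf <= 0.5:
        raise ValueError(f"MAF must be in (0, 0.5], got {maf}")
    if maf < 0.005:
        return MafBin.ULTRA_RARE
    if maf < 0.01:
        return MafBin.RARE
    if maf < 0.05:
        return MafBin.LOW_FREQUENCY
    return MafBin.COMMON


def assign_quality_bin(r2: float) -> QualityBin:
    """Map an imputation R^2 to low (<0.3) / medium ([0.3, 0.8]) / high (>0.8)."""
    if not 0 <= r2 <= 1:
        raise ValueError(f"R^2 must be in [0, 1], got {r2}")
    if r2 < 0.3:
        return QualityBin.LOW
    if r2 > 0.8:
        return QualityBin.HIGH
    return QualityBin.MEDIUM


@dataclass
class QualitySummary:
    """Counts and within-MAF-bin proportions of quality bins."""

    counts: pd.DataFrame  # MAF bin x quality bin, zeros included
    proportions: pd.DataFrame  # occupied MAF bins only; rows sum to 1


def summarize_quality(variants: pd.DataFrame) -> QualitySummary:
    """Cross-tabulate imputed variants by MAF bin and quality bin.

    ``variants`` needs ``maf`` and ``r2`` columns. Counts include empty cells
    as zeros; proportion rows are emitted only for occupied MAF bins.
    """
    maf_labels = [b.value for b in MafBin]
    q_labels = [b.value for b in QualityBin]
    counts = pd.DataFrame(0, index=maf_labels, columns=q_labels, dtype=int)
    for maf, r2 in zip(variants["maf"], variants["r2"]):
        counts.loc[assign_maf_bin(float(maf)).value, assign_quality_bin(float(r2)).value] += 1
    row_tot = counts.sum(axis=1)
    occupied = row_tot > 0
    props = counts.loc[occupied].div(row_tot[occupied], axis=0)
    return QualitySummary(counts=counts, proportions=props)


def mask_hom_ref(table: GenotypeTable) -> GenotypeTable:
    """Set homozygous-reference calls (0/0) to missing (./.); idempotent."""
    out = table.copy()
    out.gt[out.gt == 0] = MISSING
    return out


@dataclass
class ConcordanceResult:
    """Per-sample genotype concordance between two callsets."""

    per_sample: pd.DataFrame  # sample, compared, discordant, concordance
    mean_concordance: float  # over samples with >= 1 comparable genotype
    n_shared_variants: int


def per_individual_concordance(
    a: GenotypeTable, b: GenotypeTable, maf_bin: MafBin | None = None
) -> ConcordanceResult:
    """Per-individual concordance over shared samples and variants.

    Variants are matched on (chrom, pos, ref, alt); samples by name. When
    ``maf_bin`` is given and ``a`` carries a ``maf`` column, comparison is
    restricted to variants in that bin; for the ultra-rare and rare bins,
    hom-ref masking is applied to both callsets first. A sample with zero
    comparable genotypes gets NaN concordance and is excluded from the mean.
    """
    shared_samples = [s for s in a.samples if s in set(b.samples)]
    if not shared_samples:
        raise ValueError("no shared samples between callsets")
    ka, kb = a.variant_keys(), b.variant_keys()
    shared = ka.intersection(kb)
    ia = ka.get_indexer_for(shared)
    ib = kb.get_indexer_for(shared)

    if maf_bin is not None and "maf" in a.variants.columns:
        mafs = a.variants["maf"].to_numpy()[ia]
        keep = np.array([assign_maf_bin(float(m)) is maf_bin for m in mafs])
        ia, ib = ia[keep], ib[keep]

    if maf_bin in MASKED_BINS:
        a, b = mask_hom_ref(a), mask_hom_ref(b)

    ja = [a.samples.index(s) for s in shared_samples]
    jb = [b.samples.index(s) for s in shared_samples]
    ga = a.gt[np.ix_(ia, ja)]
    gb = b.gt[np.ix_(ib, jb)]
    both = (ga != MISSING) & (gb != MISSING)
    compared = both.sum(axis=0)
    discordant = (both & (ga != gb)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        conc = np.where(compared > 0, 1.0 - discordant / np.maximum(compared, 1), np.nan)
    per_sample = pd.DataFrame(
        {
            "sample": shared_samples,
            "compared": compared,
            "discordant": discordant,
            "concordance": conc,
        }
    )
    mean = float(np.nanmean(conc)) if np.isfinite(conc).any() else float("nan")
    return ConcordanceResult(per_sample=per_sample, mean_concordance=mean,
                             n_shared_variants=len(ia))
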