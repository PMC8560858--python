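"""GWAS-catalog filtering and per-array marker coverage.

The association catalog is reduced to well-supported disease markers by a
fixed sequence of criteria: effect size (OR) reported, risk-allele frequency
reported, genome-wide significance (p <= 5e-8, inclusive), de-duplication of
repeated phenotype-locus associations, case-control design, disease
phenotype, and journal 2019 impact factor > 5. Each step's removals are
recorded so the reduction is fully auditable.

Coverage of the surviving markers by an array counts a marker as genotyped
when the array assays its position, or as callable by imputation when it
appears in an imputed callset with R^2 > 0.8 (the stringent clinical-grade
cutoff, not the GWAS convention of 0.3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imputation_eval import ImputedCallset
from .manifests import ArrayManifest

logger = logging.getLogger(__name__)

DEFAULT_P_MAX = 5e-8
DEFAULT_IF_MIN = 5.0
DEFAULT_R2_MIN = 0.8

#: catalog frame columns
CATALOG_COLUMNS = [
    "rsid", "trait", "p_value", "odds_ratio", "risk_allele_freq",
    "study_design", "trait_class", "journal_if_2019",
]

#: trait keywords treated as non-disease when no explicit class is given
DEFAULT_NON_DISEASE_KEYWORDS = (
    "hair color", "hair colour", "eye color", "eye colour", "skin pigmentation",
    "height", "body mass index", "educational attainment", "intelligence",
    "handedness", "morning person", "chronotype", "freckl",
)

#: filter criteria in application order
FILTER_STEPS = (
    "or_missing", "raf_missing", "p_value", "duplicate",
    "not_case_control", "non_disease", "impact_factor",
)


@dataclass
class FilterReport:
    """Per-criterion removal counts in application order."""

    input_count: int
    removed: dict[str, int]
    output_count: int

    def __post_init__(self) -> None:
        if self.output_count != self.input_count - sum(self.removed.values()):
            raise ValueError("filter report does not reconcile")

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.input_count)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        rows.append(("output", self.output_count))
        return pd.DataFrame(rows, columns=["step", "count"])


def classify_trait(trait: str, non_disease_keywords=DEFAULT_NON_DISEASE_KEYWORDS) -> str:
    """Keyword-blocklist trait classification: 'disease' unless matched."""
    t = trait.lower()
    return "non_disease" if any(k in t for k in non_disease_keywords) else "disease"


def filter_catalog(
    records: pd.DataFrame,
    p_max: float = DEFAULT_P_MAX,
    if_min: float = DEFAULT_IF_MIN,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the marker-selection criteria in their fixed order.

    Keeps records with odds ratio and risk-allele frequency present,
    p <= ``p_max`` (inclusive), one record per (trait, rsid) pair (smallest
    p wins; ties by rsid order are moot within a pair, so the first stable
    occurrence is kept), case-control design, disease trait class, and
    journal impact factor > ``if_min`` (strict).
    """
    df = records.reset_index(drop=True)
    removed: dict[str, int] = {}

    def drop(mask_keep: pd.Series, step: str) -> None:
        nonlocal df
        removed[step] = int((~mask_keep).sum())
        df = df.loc[mask_keep]

    input_count = len(df)
    drop(df["odds_ratio"].notna(), "or_missing")
    drop(df["risk_allele_freq"].notna(), "raf_missing")
    drop(df["p_value"] <= p_max, "p_value")

    # de-duplicate identical phenotype-locus associations, smallest p first
    order = df.sort_values(["trait", "rsid", "p_value"], kind="stable")
    first = ~order.duplicated(subset=["trait", "rsid"], keep="first")
    keep_idx = order.index[first]
    drop(pd.Series(df.index.isin(keep_idx), index=df.index), "duplicate")

    drop(df["study_design"] == "case_control", "not_case_control")
    drop(df["trait_class"] == "disease", "non_disease")
    drop(df["journal_if_2019"].notna() & (df["journal_if_2019"] > if_min), "impact_factor")

    report = FilterReport(input_count=input_count, removed=removed, output_count=len(df))
    return df.reset_index(drop=True), report


def read_catalog_tsv(
    path: str,
    if_table: pd.DataFrame | None = None,
    non_disease_keywords=DEFAULT_NON_DISEASE_KEYWORDS,
) -> pd.DataFrame:
    """Read a GWAS-catalog association export into the canonical frame.

    Accepts either the canonical columns (see :data:`CATALOG_COLUMNS`) or the
    standard catalog download headers (``SNPS``, ``DISEASE/TRAIT``,
    ``P-VALUE``, ``OR or BETA``, ``RISK ALLELE FREQUENCY``, ``JOURNAL``,
    optionally ``STUDY DESIGN``). ``if_table`` maps journal name to 2019
    impact factor (columns ``journal, impact_factor``); trait class is
    derived from the keyword blocklist when absent.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if "rsid" in raw.columns:
        df = raw.copy()
    else:
        df = pd.DataFrame(
            {
                "rsid": raw.get("SNPS"),
                "trait": raw.get("DISEASE/TRAIT"),
                "p_value": raw.get("P-VALUE"),
                "odds_ratio": raw.get("OR or BETA"),
                "risk_allele_freq": raw.get("RISK ALLELE FREQUENCY"),
                "study_design": raw.get("STUDY DESIGN"),
                "journal": raw.get("JOURNAL"),
            }
        )
    for col in ("p_value", "odds_ratio", "risk_allele_freq"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if "journal_if_2019" not in df.columns:
        if if_table is not None and "journal" in df.columns:
            lut = dict(zip(if_table["journal"], if_table["impact_factor"]))
            df["journal_if_2019"] = pd.to_numeric(
                df["journal"].map(lut), errors="coerce"
            )
        else:
            df["journal_if_2019"] = np.nan
    if "trait_class" not in df.columns or df["trait_class"].isna().all():
        df["trait_class"] = df["trait"].fillna("").map(
            lambda t: classify_trait(t, non_disease_keywords)
        )
    if "study_design" not in df.columns:
        df["study_design"] = pd.NA
    return df[[c for c in CATALOG_COLUMNS if c in df.columns]
              + [c for c in df.columns if c not in CATALOG_COLUMNS]]


def append_extra_markers(markers: pd.DataFrame, extras: pd.DataFrame) -> pd.DataFrame:
    """Append hand-picked markers (rsid + position) not already present.

    Used for causal variants of special interest that the filtered catalog
    misses, e.g. the two APOE*4-defining SNVs added to the 6,054 filtered
    markers to give 6,056.
    """
    present = set(markers["rsid"])
    novel = extras.loc[~extras["rsid"].isin(present)]
    return pd.concat([markers, novel], ignore_index=True)


@dataclass(frozen=True)
class MarkerCoverage:
    """How much of a marker list an array covers, directly or via imputation."""

    n_markers: int
    n_genotyped: int
    n_imputed_high: int
    fraction_genotyped: float
    fraction_covered: float


def marker_coverage(
    markers: pd.DataFrame,
    manifest: ArrayManifest,
    imputed: ImputedCallset | None = None,
    r2_min: float = DEFAULT_R2_MIN,
) -> MarkerCoverage:
    """Classify each marker as genotyped, imputed at high quality, or uncovered.

    A marker is genotyped when the array assays its (chrom, pos); otherwise
    it is covered when the imputed callset contains its position with
    R^2 > ``r2_min`` (strict). Markers whose position cannot be resolved are
    counted uncovered and logged.
    """
    n = len(markers)
    if n == 0:
        raise ValueError("empty marker list")
    array_pos = manifest.positions
    imp_r2: dict[tuple[str, int], float] = {}
    if imputed is not None:
        for (c, p), r2 in zip(
            zip(imputed.variants["chrom"], imputed.variants["pos"].astype(int)),
            imputed.variants["r2"],
        ):
            imp_r2[(c, p)] = max(imp_r2.get((c, p), 0.0), float(r2))
    n_geno = n_imp = 0
    for _, row in markers.iterrows():
        if pd.isna(row.get("chrom")) or pd.isna(row.get("pos")):
            logger.warning("marker %s has no resolvable position; counted uncovered",
                           row.get("rsid"))
            continue
        key = (str(row["chrom"]), int(row["pos"]))
        if key in array_pos:
            n_geno += 1
        elif imp_r2.get(key, 0.0) > r2_min:
            n_imp += 1
    return MarkerCoverage(
        n_markers=n,
        n_genotyped=n_geno,
        n_imputed_high=n_imp,
        fraction_genotyped=n_geno / n,
        fraction_covered=(n_geno + n_imp) / n,
    )
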