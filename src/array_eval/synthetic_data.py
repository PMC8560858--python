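"""Seed-deterministic generators for every input the evaluation needs.

The panel generator uses a block-copy founder model: the genome is a series
of LD blocks; within a block each haplotype copies one of K founder
haplotypes and then flips alleles at a small mutation rate. Within-block LD
is therefore high and analytically known (r^2 = 1 between any two
polymorphic sites when K = 2 and mutation is off), while between-block LD is
~0. Ancestries differ by their founder-choice weights, giving
ancestry-specific allele frequencies and LD. This is deliberately not a
coalescent: analytic expectations make coverage tests exact.

Every generator is deterministic given (config, seed) and emits
machine-readable truth alongside the data, so tests never re-derive truth
from the data itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog_coverage import CATALOG_COLUMNS
from .coverage import HaplotypePanel
from .gene_content import StarAllele
from .imputation_eval import GenotypeTable, ImputedCallset, MISSING
from .manifests import ArrayManifest, MANIFEST_COLUMNS

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Knobs of the block-copy simulator.

    Defaults give a 5,000-SNV panel (250 blocks x 20 SNVs) for 200 EUR
    diploids with two complementary founders per block — the desk-scale
    study conditions used throughout the test suite. ``recomb_prob`` is the
    probability of re-drawing the founder between adjacent blocks (1.0 =
    independent blocks). The imputation-quality model draws R^2 from a Beta
    distribution whose mean follows a logistic link in log10(MAF), so
    quality degrades as variants get rarer.
    """

    seed: int = 0
    n_samples: dict[str, int] = field(default_factory=lambda: {"EUR": 200})
    n_blocks: int = 250
    block_length: int = 50_000
    snvs_per_block: int = 20
    n_founders: int = 2
    recomb_prob: float = 1.0
    mutation_rate: float = 0.002
    maf_floor: float = 0.01
    weight_concentration: float = 5.0
    founder_allele_beta: tuple[float, float] = (0.5, 0.5)
    r2_link_intercept: float = 3.5
    r2_link_slope: float = 1.7
    r2_concentration: float = 20.0
    wes_flip_rate: float = 0.01

    def __post_init__(self) -> None:
        for p in (self.recomb_prob, self.mutation_rate, self.maf_floor, self.wes_flip_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for c in (self.n_blocks, self.block_length, self.snvs_per_block,
                  self.n_founders, *self.n_samples.values()):
            if c < 1:
                raise ValueError("all counts must be >= 1")


def _random_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref = _BASES[rng.integers(0, 4, size=n)]
    alt = _BASES[(np.char.find("".join(_BASES), ref.astype("U1")).astype(int)
                  + rng.integers(1, 4, size=n)) % 4]
    return ref, alt


def simulate_panel(cfg: SimConfig) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Generate a phased multi-ancestry panel plus a per-variant truth table.

    Truth columns: ``block`` (LD-block id) and ``expected_freq_<ancestry>``
    (analytic alternate-allele frequency under the founder weights and
    mutation rate).
    """
    rng = np.random.default_rng(cfg.seed)
    B, m, K = cfg.n_blocks, cfg.snvs_per_block, cfg.n_founders
    n_var = B * m

    # positions: blocks laid back to back on chromosome 1
    positions = np.empty(n_var, dtype=np.int64)
    for b in range(B):
        offs = np.sort(rng.choice(cfg.block_length, size=m, replace=False))
        positions[b * m:(b + 1) * m] = b * cfg.block_length + offs + 1
    ref, alt = _random_alleles(rng, n_var)
    variants = pd.DataFrame({
        "chrom": "1", "pos": positions, "ref": ref, "alt": alt,
    })
    blocks = np.repeat(np.arange(B), m)

    # founders: (B, K, m); K=2 founders are complementary so every SNV segregates
    if K == 2:
        f0 = rng.integers(0, 2, size=(B, 1, m), dtype=np.uint8)
        founders = np.concatenate([f0, 1 - f0], axis=1)
    else:
        base_freq = rng.beta(*cfg.founder_allele_beta, size=(B, 1, m))
        founders = (rng.random(size=(B, K, m)) < base_freq).astype(np.uint8)

    samples: list[str] = []
    ancestry: list[str] = []
    hap_chunks: list[np.ndarray] = []
    truth = pd.DataFrame({"block": blocks})
    for anc in sorted(cfg.n_samples):
        n = cfg.n_samples[anc]
        weights = rng.dirichlet(np.full(K, cfg.weight_concentration), size=B)  # (B, K)
        n_h = 2 * n
        hap = np.empty((n_h, n_var), dtype=np.uint8)
        # founder-index chain across blocks
        idx = np.empty((n_h, B), dtype=np.int64)
        for b in range(B):
            draw = _categorical(rng, weights[b], n_h)
            if b == 0:
                idx[:, b] = draw
            else:
                redo = rng.random(n_h) < cfg.recomb_prob
                idx[:, b] = np.where(redo, draw, idx[:, b - 1])
            hap[:, b * m:(b + 1) * m] = founders[b, idx[:, b], :]
        flips = rng.random(hap.shape) < cfg.mutation_rate
        hap ^= flips.astype(np.uint8)
        hap_chunks.append(hap)
        samples += [f"{anc}{i:04d}" for i in range(n)]
        ancestry += [anc] * n
        p_founder = np.einsum("bk,bkm->bm", weights, founders).reshape(n_var)
        truth[f"expected_freq_{anc}"] = (
            p_founder * (1 - cfg.mutation_rate) + (1 - p_founder) * cfg.mutation_rate
        )

    panel = HaplotypePanel(
        variants=variants,
        haplotypes=np.vstack(hap_chunks),
        samples=samples,
        sample_ancestry=np.array(ancestry, dtype=object),
    )
    return panel, truth


def _categorical(rng: np.random.Generator, w: np.ndarray, size: int) -> np.ndarray:
    return np.searchsorted(np.cumsum(w), rng.random(size), side="right").clip(0, len(w) - 1)


@dataclass
class ManifestTruth:
    """Design record of a simulated array: what it was built to tag."""

    covered_blocks: np.ndarray
    tag_variant_idx: np.ndarray  # panel row indices of tag SNVs
    designed_fraction: float


def simulate_manifest(
    panel: HaplotypePanel,
    truth: pd.DataFrame,
    tags_per_block: int = 1,
    frac_blocks: float = 1.0,
    off_panel_snvs: int = 0,
    seed: int = 0,
    name: str = "sim_array",
    min_tag_maf: float = 0.05,
) -> tuple[ArrayManifest, ManifestTruth]:
    """Design a tag-SNV array over a simulated panel.

    Picks ``tags_per_block`` tag SNVs in a fraction ``frac_blocks`` of the
    LD blocks (tags drawn among common SNVs so they survive MAF filtering),
    plus ``off_panel_snvs`` probes at positions absent from the panel. The
    returned truth records which blocks are covered, so the expected tagged
    fraction is analytic.
    """
    if tags_per_block > panel.variants.groupby(truth["block"]).size().min():
        raise ValueError("tags_per_block exceeds SNVs per block")
    rng = np.random.default_rng(seed)
    blocks = np.unique(truth["block"])
    n_cov = int(round(frac_blocks * len(blocks)))
    covered = rng.choice(blocks, size=n_cov, replace=False)
    maf = panel.maf
    tag_idx: list[int] = []
    for b in covered:
        rows = np.where(truth["block"].to_numpy() == b)[0]
        common = rows[maf[rows] >= min_tag_maf]
        pool = common if len(common) >= tags_per_block else rows[np.argsort(maf[rows])[::-1]]
        tag_idx.extend(rng.choice(pool, size=tags_per_block, replace=False))
    tag_idx = np.sort(np.asarray(tag_idx, dtype=int))

    df = panel.variants.iloc[tag_idx][["chrom", "pos", "ref", "alt"]].copy()
    df["probe_class"] = "snv"
    df["functional"] = "other"
    if off_panel_snvs:
        max_pos = int(panel.variants["pos"].max())
        pos = max_pos + 1 + np.sort(rng.choice(10 * off_panel_snvs, size=off_panel_snvs,
                                               replace=False))
        ref, alt = _random_alleles(rng, off_panel_snvs)
        extra = pd.DataFrame({
            "chrom": "2", "pos": pos, "ref": ref, "alt": alt,
            "probe_class": "snv", "functional": "other",
        })
        df = pd.concat([df, extra], ignore_index=True)
    manifest = ArrayManifest(name=name, df=df[MANIFEST_COLUMNS])
    return manifest, ManifestTruth(
        covered_blocks=np.sort(covered),
        tag_variant_idx=tag_idx,
        designed_fraction=float(frac_blocks),
    )


def simulate_imputed(
    panel: HaplotypePanel,
    manifest: ArrayManifest,
    cfg: SimConfig,
    seed: int | None = None,
) -> ImputedCallset:
    """Emulate an imputation-service callset over the panel's variants.

    On-array variants get R^2 = 1; off-array variants draw R^2 from a Beta
    distribution whose mean follows sigmoid(intercept + slope * log10(MAF)),
    so rarer variants impute worse. Genotypes are the panel's diploid calls.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    maf = panel.maf
    floor = 1.0 / (2 * len(panel.samples))
    maf_eff = np.maximum(maf, floor)
    mean = 1.0 / (1.0 + np.exp(-(cfg.r2_link_intercept
                                 + cfg.r2_link_slope * np.log10(maf_eff))))
    nu = cfg.r2_concentration
    r2 = rng.beta(np.maximum(mean * nu, 1e-6), np.maximum((1 - mean) * nu, 1e-6))
    pos_set = manifest.positions
    on_array = np.fromiter(
        ((c, int(p)) in pos_set
         for c, p in zip(panel.variants["chrom"], panel.variants["pos"])),
        dtype=bool, count=len(maf),
    )
    r2[on_array] = 1.0
    variants = panel.variants[["chrom", "pos", "ref", "alt"]].copy()
    variants["r2"] = r2
    variants["maf"] = maf
    return GenotypeTable(variants=variants, samples=list(panel.samples),
                         gt=panel.genotypes().astype(np.int8))


def simulate_wes_pair(
    truth: GenotypeTable, flip_rate: float, seed: int = 0
) -> tuple[GenotypeTable, GenotypeTable]:
    """An (imputed-style, WES) callset pair with a known genotype-flip rate.

    The WES copy flips each non-missing genotype to one of the other two
    states with probability ``flip_rate``, so the expected per-genotype
    discordance equals ``flip_rate`` exactly.
    """
    rng = np.random.default_rng(seed)
    imputed = truth.copy()
    wes = truth.copy()
    flip = (rng.random(wes.gt.shape) < flip_rate) & (wes.gt != MISSING)
    shift = rng.integers(1, 3, size=wes.gt.shape)
    wes.gt[flip] = ((wes.gt[flip].astype(int) + shift[flip]) % 3).astype(np.int8)
    return imputed, wes


def simulate_star_alleles(
    manifest: ArrayManifest,
    n_genes: int = 12,
    alleles_per_gene: int = 10,
    frac_callable: float = 0.5,
    seed: int = 0,
    max_tags: int = 3,
    ancestries: tuple[str, ...] = ("all",),
) -> tuple[list[StarAllele], pd.DataFrame]:
    """Star-allele definitions with known callable truth.

    Each allele is planted callable with probability ``frac_callable``:
    callable alleles draw every tag SNV from the manifest; the rest get at
    least one tag at a position absent from the array. Truth columns:
    gene, allele, ancestry, callable.
    """
    rng = np.random.default_rng(seed)
    on_keys = sorted(manifest.allele_keys)
    if not on_keys:
        raise ValueError("manifest has no variants to draw tags from")
    max_pos = int(manifest.df["pos"].max())
    alleles: list[StarAllele] = []
    rows: list[dict] = []
    off_counter = 0
    for gi in range(n_genes):
        gene = f"GENE{gi + 1}"
        for ai in range(alleles_per_gene):
            for anc in ancestries:
                callable_ = bool(rng.random() < frac_callable)
                n_tags = int(rng.integers(1, max_tags + 1))
                picks = [on_keys[k] for k in rng.choice(len(on_keys), size=n_tags,
                                                        replace=False)]
                if not callable_:
                    off_counter += 1
                    ref, alt = _random_alleles(rng, 1)
                    picks[int(rng.integers(0, n_tags))] = (
                        "3", max_pos + off_counter, str(ref[0]), str(alt[0]))
                alleles.append(StarAllele(gene=gene, allele=f"*{ai + 2}",
                                          tag_snvs=picks, ancestry=anc))
                rows.append(dict(gene=gene, allele=f"*{ai + 2}", ancestry=anc,
                                 callable=callable_))
    return alleles, pd.DataFrame(rows)


def simulate_catalog(
    n_records: int,
    failure_probs: dict[str, float] | None = None,
    n_duplicates: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """A GWAS-catalog-style table with planted single-criterion failures.

    ``failure_probs`` maps a filter step (``or_missing, raf_missing,
    p_value, not_case_control, non_disease, impact_factor``) to the
    probability a record is planted to fail exactly that step; the rest
    pass every criterion. ``n_duplicates`` extra copies of passing records
    (with larger p) are appended and fall to the de-duplication step.
    Returns the table plus the planted per-step truth counts, including
    ``survivors``.
    """
    steps = ["or_missing", "raf_missing", "p_value",
             "not_case_control", "non_disease", "impact_factor"]
    failure_probs = failure_probs or {}
    unknown = set(failure_probs) - set(steps)
    if unknown:
        raise ValueError(f"unknown filter steps: {sorted(unknown)}")
    probs = np.array([failure_probs.get(s, 0.0) for s in steps])
    if probs.sum() > 1:
        raise ValueError("failure probabilities sum beyond 1")
    rng = np.random.default_rng(seed)
    fate = _categorical(rng, np.append(probs, 1 - probs.sum()), n_records)
    rows: list[dict] = []
    truth = {s: 0 for s in steps}
    for i in range(n_records):
        rec = dict(
            rsid=f"rs{i + 1}",
            trait=f"trait_{i + 1}",
            p_value=float(10 ** rng.uniform(-20, np.log10(5e-8))),
            odds_ratio=float(np.exp(rng.normal(0.3, 0.2))),
            risk_allele_freq=float(rng.uniform(0.01, 0.5)),
            study_design="case_control",
            trait_class="disease",
            journal_if_2019=float(rng.uniform(6, 50)),
            chrom=str(rng.integers(1, 23)),
            pos=int(rng.integers(1, 10_000_000)),
        )
        if fate[i] < len(steps):
            step = steps[fate[i]]
            truth[step] += 1
            if step == "or_missing":
                rec["odds_ratio"] = np.nan
            elif step == "raf_missing":
                rec["risk_allele_freq"] = np.nan
            elif step == "p_value":
                rec["p_value"] = float(10 ** rng.uniform(-6, -3))
            elif step == "not_case_control":
                rec["study_design"] = "cohort"
            elif step == "non_disease":
                rec["trait_class"] = "non_disease"
            elif step == "impact_factor":
                rec["journal_if_2019"] = float(rng.uniform(0.5, 5.0))
        rows.append(rec)
    passing = [r for r in rows if not np.isnan(r["odds_ratio"])
               and not np.isnan(r["risk_allele_freq"])
               and r["p_value"] <= 5e-8 and r["study_design"] == "case_control"
               and r["trait_class"] == "disease" and r["journal_if_2019"] > 5]
    truth["duplicate"] = 0
    if n_duplicates:
        if not passing:
            raise ValueError("cannot plant duplicates without passing records")
        for k in range(n_duplicates):
            src = passing[int(rng.integers(0, len(passing)))]
            dup = dict(src)
            dup["p_value"] = min(5e-8, src["p_value"] * 10)  # worse p, still significant
            rows.append(dup)
            truth["duplicate"] += 1
    truth["survivors"] = len(passing)
    df = pd.DataFrame(rows, columns=CATALOG_COLUMNS + ["chrom", "pos"])
    return df, truth
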