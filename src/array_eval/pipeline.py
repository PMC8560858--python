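"""End-to-end orchestration: one config in, a directory of report tables out.

``run_all`` executes the enabled stages in dependency order on a synthetic
dataset generated from the config's seed (or on user-supplied inputs where
paths are given), writing one TSV per comparison. Every output carries
comment-header lines naming the thresholds used, and a rerun with the same
config and seed produces byte-identical tables.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import catalog_coverage as cat
from . import coverage as cov
from . import gene_content as gc
from . import imputation_eval as imp
from . import manifests as man
from . import synthetic_data as sim
from . import vcfio

logger = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1

ALL_STAGES = ("manifest", "coverage", "imputation", "catalog", "genes")


@dataclass
class RunConfig:
    """Thresholds, input paths and simulation scale for one full run."""

    seed: int = 0
    out_dir: str = "array_eval_report"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))

    # thresholds (defaults are the study-wide conventions)
    min_maf: float = 0.01
    r2_tag: float = 0.8
    r2_impute_high: float = 0.8
    r2_impute_low: float = 0.3
    cadd_min: float = 20.0
    p_max: float = 5e-8
    if_min: float = 5.0
    call_rate_min: float = 0.975
    hwe_p_min: float = 1e-7
    genome_snvs: int = 19_000_000
    window_bp: int = 1_000_000

    # optional real inputs; when None the synthetic generators stand in
    manifest_paths: dict[str, str] | None = None  # name -> BED path
    panel_vcf: str | None = None
    ancestry_map: str | None = None
    imputed_vcf: str | None = None
    wes_vcf: str | None = None
    catalog_tsv: str | None = None

    # synthetic scale (used when inputs above are absent)
    sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        for name, lo, hi, v in [
            ("min_maf", 0, 0.5, self.min_maf), ("r2_tag", 0, 1, self.r2_tag),
            ("r2_impute_high", 0, 1, self.r2_impute_high),
            ("r2_impute_low", 0, 1, self.r2_impute_low),
            ("p_max", 0, 1, self.p_max),
            ("call_rate_min", 0, 1, self.call_rate_min),
            ("hwe_p_min", 0, 1, self.hwe_p_min),
        ]:
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _write_tsv(df: pd.DataFrame, path: Path, params: dict, index: bool = True) -> None:
    with open(path, "w") as fh:
        for k, v in params.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_all(cfg: RunConfig) -> Path:
    """Run every enabled stage; returns the report directory.

    Missing inputs for an enabled stage are reported before any computation;
    with no inputs configured, the synthetic generators supply a coherent
    dataset at the config's seed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    logger.info("array-eval %s | config schema v%d | seed %d",
                __version__, CONFIG_SCHEMA_VERSION, cfg.seed)

    synthetic = cfg.panel_vcf is None
    if not synthetic and cfg.ancestry_map is None and "coverage" in cfg.stages:
        raise FileNotFoundError("coverage stage needs an ancestry map alongside the panel VCF")
    for p in (cfg.panel_vcf, cfg.ancestry_map, cfg.imputed_vcf, cfg.wes_vcf, cfg.catalog_tsv):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(p)

    scfg = sim.SimConfig(seed=cfg.seed, **cfg.sim)
    if synthetic:
        panel, panel_truth = sim.simulate_panel(scfg)
        manifest_a, _ = sim.simulate_manifest(panel, panel_truth, frac_blocks=0.6,
                                              seed=cfg.seed + 1, name="dense_array")
        manifest_b, _ = sim.simulate_manifest(panel, panel_truth, frac_blocks=0.25,
                                              seed=cfg.seed + 2, name="sparse_array")
        manifests = [manifest_a, manifest_b]
    else:
        panel = vcfio.read_panel_vcf(cfg.panel_vcf, vcfio.read_ancestry_map(cfg.ancestry_map))
        panel_truth = None
        manifests = [man.read_manifest(p, name, format="bed")
                     for name, p in (cfg.manifest_paths or {}).items()]
        if not manifests:
            raise FileNotFoundError("no manifest paths configured")
    primary = manifests[0]

    thresholds = dict(
        seed=cfg.seed, min_maf=cfg.min_maf, r2_tag=cfg.r2_tag,
        r2_impute_high=cfg.r2_impute_high, r2_impute_low=cfg.r2_impute_low,
        cadd_min=cfg.cadd_min, p_max=cfg.p_max, if_min=cfg.if_min,
        call_rate_min=cfg.call_rate_min, hwe_p_min=cfg.hwe_p_min,
        genome_snvs=cfg.genome_snvs, window_bp=cfg.window_bp,
    )

    if "manifest" in cfg.stages:
        summaries = pd.concat([man.summarize_content(m).to_frame() for m in manifests])
        _write_tsv(summaries, out / "content_summary.tsv", thresholds)
        ov = man.overlap_matrix(manifests)
        _write_tsv(ov.counts, out / "overlap.tsv", thresholds)

    if "coverage" in cfg.stages:
        rows = []
        for m in manifests:
            results = cov.coverage_by_ancestry(
                m, panel, G=cfg.genome_snvs, r2_min=cfg.r2_tag,
                window_bp=cfg.window_bp, min_maf=cfg.min_maf)
            for anc, r in results.items():
                rows.append(dict(array=m.name, ancestry=anc, L=r.L, R=r.R, T=r.T,
                                 G=r.G, cr=r.cr))
        _write_tsv(pd.DataFrame(rows), out / "coverage.tsv", thresholds, index=False)
        tg = [dict(ancestry=a,
                   taggability=cov.taggability(
                       cov.filter_panel_by_maf(panel, a, cfg.min_maf),
                       r2_min=cfg.r2_tag, window_bp=cfg.window_bp))
              for a in panel.ancestries]
        _write_tsv(pd.DataFrame(tg), out / "taggability.tsv", thresholds, index=False)

    imputed = None
    if "imputation" in cfg.stages or "catalog" in cfg.stages or "genes" in cfg.stages:
        if cfg.imputed_vcf:
            imputed = vcfio.read_genotype_vcf(cfg.imputed_vcf)
        elif synthetic:
            imputed = sim.simulate_imputed(panel, primary, scfg, seed=cfg.seed + 3)

    if "imputation" in cfg.stages:
        if imputed is None:
            raise FileNotFoundError("imputation stage needs an imputed VCF")
        qs = imp.summarize_quality(imputed.variants)
        _write_tsv(qs.counts, out / "imputation_bin_counts.tsv", thresholds)
        _write_tsv(qs.proportions, out / "imputation_bin_proportions.tsv", thresholds)
        if cfg.wes_vcf:
            wes = vcfio.read_genotype_vcf(cfg.wes_vcf)
        else:
            _, wes = sim.simulate_wes_pair(imputed, scfg.wes_flip_rate, seed=cfg.seed + 4)
        rows = []
        for b in imp.MafBin:
            res = imp.per_individual_concordance(imputed, wes, maf_bin=b)
            rows.append(dict(maf_bin=b.value, n_variants=res.n_shared_variants,
                             mean_concordance=res.mean_concordance))
        _write_tsv(pd.DataFrame(rows), out / "concordance.tsv", thresholds, index=False)

    if "catalog" in cfg.stages:
        if cfg.catalog_tsv:
            records = cat.read_catalog_tsv(cfg.catalog_tsv)
        else:
            records, _ = sim.simulate_catalog(
                2000, failure_probs={"or_missing": 0.1, "raf_missing": 0.1,
                                     "p_value": 0.1, "not_case_control": 0.1,
                                     "non_disease": 0.1, "impact_factor": 0.1},
                n_duplicates=20, seed=cfg.seed + 5)
        markers, report = cat.filter_catalog(records, p_max=cfg.p_max, if_min=cfg.if_min)
        _write_tsv(report.to_frame(), out / "catalog_filter_report.tsv", thresholds,
                   index=False)
        rows = []
        for m in manifests:
            mc = cat.marker_coverage(markers, m, imputed, r2_min=cfg.r2_impute_high)
            rows.append(dict(array=m.name, **asdict(mc)))
        _write_tsv(pd.DataFrame(rows), out / "marker_coverage.tsv", thresholds, index=False)

    if "genes" in cfg.stages:
        alleles, _ = sim.simulate_star_alleles(primary, seed=cfg.seed + 6)
        rows = []
        for gene in sorted({a.gene for a in alleles}):
            pct_arr = gc.percent_star_alleles(gene, alleles, primary)
            pct_imp = gc.percent_star_alleles(gene, alleles, primary, imputed,
                                              r2_min=cfg.r2_impute_high)
            rows.append(dict(gene=gene, pct_callable_array=pct_arr,
                             pct_callable_imputed=pct_imp))
        _write_tsv(pd.DataFrame(rows), out / "star_alleles.tsv", thresholds, index=False)
        chrom_lengths = {c: int(primary.df.loc[primary.df["chrom"] == c, "pos"].max())
                         for c in sorted(primary.df["chrom"].unique())}
        dens = gc.window_density(primary, cfg.window_bp, chrom_lengths)
        _write_tsv(pd.DataFrame([dict(window_bp=dens.window_bp, mean=dens.mean,
                                      sd=dens.sd)]),
                   out / "window_density.tsv", thresholds, index=False)

    logger.info("run complete in %.1f s -> %s", time.time() - t0, out)
    return out
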