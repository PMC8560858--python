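import numpy as np
import pandas as pd
import pytest

from array_eval.coverage import HaplotypePanel
from array_eval.imputation_eval import GenotypeTable
from array_eval.manifests import MANIFEST_COLUMNS, ArrayManifest


def make_manifest(rows, name="test_array"):
    """Build a manifest from (chrom, pos, ref, alt[, probe_class[, functional]]) tuples."""
    recs = []
    for row in rows:
        chrom, pos, ref, alt = row[:4]
        probe = row[4] if len(row) > 4 else ("cnv_intensity" if not ref else "snv")
        func = row[5] if len(row) > 5 else "other"
        recs.append(dict(chrom=chrom, pos=pos, ref=ref, alt=alt,
                         probe_class=probe, functional=func))
    return ArrayManifest(name=name, df=pd.DataFrame(recs, columns=MANIFEST_COLUMNS))


def make_panel(haplotypes, positions=None, chrom="1", ancestry=None):
    """Panel from a (2n x m) 0/1 matrix; positions default to 100, 200, ..."""
    h = np.asarray(haplotypes, dtype=np.uint8)
    n = h.shape[0] // 2
    m = h.shape[1]
    pos = positions if positions is not None else [100 * (j + 1) for j in range(m)]
    variants = pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "ref": ["A"] * m, "alt": ["G"] * m,
    })
    anc = ancestry if ancestry is not None else ["EUR"] * n
    return HaplotypePanel(variants=variants, haplotypes=h,
                          samples=[f"S{i}" for i in range(n)],
                          sample_ancestry=np.array(anc, dtype=object))


def make_genotype_table(gt, chrom="1", samples=None, maf=None, r2=None):
    """Genotype table from an (n_var x n_samp) matrix of {0,1,2,-1}."""
    g = np.asarray(gt, dtype=np.int8)
    nv, ns = g.shape
    variants = pd.DataFrame({
        "chrom": chrom, "pos": np.arange(1, nv + 1) * 10,
        "ref": ["A"] * nv, "alt": ["G"] * nv,
    })
    if maf is not None:
        variants["maf"] = maf
    if r2 is not None:
        variants["r2"] = r2
    return GenotypeTable(variants=variants,
                         samples=samples or [f"S{i}" for i in range(ns)], gt=g)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
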