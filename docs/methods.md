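# Methods

## Scope and model

`array-eval` quantifies what a genotyping array can deliver, given its
manifest and a phased reference haplotype panel: genome-wide coverage
through linkage-disequilibrium (LD) tagging, the quality profile of
downstream imputation, concordance of imputed genotypes with an orthogonal
truth set (WES), coverage of curated GWAS markers, and identifiability of
clinically used haplotypes (pharmacogene and HLA star alleles), plus
content summaries, mtDNA locus tallies and SNV-density profiles.

### Genome-wide coverage

An off-array panel SNV is *tagged* when some on-array SNV on the same
chromosome within a physical window has haplotype r² strictly above a
threshold (default 0.8). r² between two biallelic variants is the squared
correlation of their 0/1 haplotype indicators,

    r² = D² / (pA(1−pA) pB(1−pB)),  D = pAB − pA·pB,

computed from phased haplotypes; it is symmetric and invariant to swapping
the ref/alt coding of either variant, and undefined (and excluded) for
monomorphic sites. The coverage rate extrapolates tagging on the panel to
the genome:

    CR = (L/(R−T) · (G−T) + T) / G

with L the number of tagged off-array panel SNVs, R the panel SNV count
after MAF filtering, T the array's total variant count, and G an assumed
genome-wide SNV count (default 19,000,000 validated SNVs with MAF > 1%,
configurable). Coverage is computed per ancestry: the panel is first
restricted to one ancestry's samples and to variants with MAF ≥ 1%
(inclusive) recomputed within that subset.

Numerical choices: ties at exactly r² = threshold do **not** tag (strict
inequality); the LD search window defaults to 1 Mb flanking — it exists to
bound the otherwise quadratic pair search, and an oracle-equivalence test
verifies that windowed tagging equals brute-force all-pairs tagging
whenever the window spans the chromosome. L counts only panel SNVs absent
from the array (array SNVs enter through T, avoiding double counting);
array variants absent from the panel still count in T. Multi-allelic panel
sites are decomposed to biallelic records on read and indel alleles are
skipped — coverage is defined over SNVs. *Taggability* (the fraction of
panel SNVs tagged by another panel SNV) excludes self-pairs only.

### Imputation quality and concordance

Imputed variants carry a service-reported per-variant R² (we do not
recompute dosage correlations). Bins: MAF in (0, 0.5%) ultra-rare,
[0.5%, 1%) rare, [1%, 5%) low-frequency, [5%, 50%] common — the interior
boundaries are left-closed/right-open, a convention we fixed because the
printed ranges are ambiguous at the edges; quality R² < 0.3 low,
[0.3, 0.8] medium (closed, since the neighbouring classes are defined by
strict "lower than" / "higher than"), > 0.8 high. Gene-category analyses
use the stringent R² > 0.8 cutoff throughout, not the GWAS convention of
0.3, because the intended application is clinical-grade calling.

Concordance against WES is per individual, over variants matched on
(chrom, pos, ref, alt) and genotypes non-missing in both sets (half-missing
pairs are excluded from the denominator). For the ultra-rare and rare bins,
hom-ref calls are masked to missing in *both* sets first, so the metric is
driven by variant-allele genotypes only; masking is idempotent. Samples
with zero comparable genotypes are reported as undefined and excluded from
the mean.

Pre-imputation QC removes, in order: SNVs with call rate < 97.5%, samples
with call rate < 97.5%, autosomal SNVs with exact Hardy–Weinberg p < 1e-7,
and samples with excess heterozygosity. HWE uses the exact conditional
test (enumeration of heterozygote counts given allele counts, summing
configurations no more probable than the observed one); it is applied to
autosomes only — sex information is not modelled, so X is exempt rather
than mis-tested in males. The excess-heterozygosity rule — inbreeding
coefficient more than 4 SD below the cohort mean — is our concrete choice
for a criterion that is conventionally left unspecified.

### GWAS-catalog filtering

Catalog records are filtered in a fixed order: OR reported, risk-allele
frequency reported, p ≤ 5e-8 (inclusive), de-duplication of identical
(trait, rsid) associations keeping the smallest p, case-control design,
disease phenotype, journal 2019 impact factor > 5 (strict; records with no
impact factor fail). The per-step removal counts are reported so the
reduction reconciles exactly and any reordering is auditable. Duplicate
matching uses rsid (position-based matching is a noted alternative).
Disease classification is a user-supplied allow/block list; a default
blocklist of non-disease trait keywords ships with the package. Marker
coverage classifies each marker as genotyped (array assays its position),
imputed at high quality (R² > 0.8), or uncovered.

### Gene-category metrics

Gene membership is positional: a variant counts for every gene whose
merged CDS intervals (1-based, ends inclusive) contain its position;
alleles are ignored at this step, and one principal transcript per gene is
expected in the input table. Proxy-deleterious counting keeps variants
with CADD phred strictly above 20 matched on full allele identity; the
median and IQR are taken over the whole gene list, zero-count genes
included, and a distinct-variant total is reported separately because
overlapping genes double-count.

Star-allele identifiability is all-or-nothing: an allele is callable only
if every tag SNV of its defining haplotype is assayed (position + allele
identity after normalization; position-only matching is available behind a
flag). In imputed mode a tag SNV may instead be covered at R² > 0.8; this
evaluates *identifiability*, not sample-level calls, so only per-variant
R² is inspected. CNV-defined alleles (whole-gene deletions/duplications)
are not evaluable — calling them needs intensity-based CNV analysis, which
is out of scope. HLA tag sets are ancestry-specific, so HLA percentages
are computed per ancestry with a per-gene mean and population SD across
ancestries; we report allele-level percentages only (population-level
carrier coverage is a different quantity).

mtDNA loci overlap, so per-locus tallies can sum to more than the distinct
MT-variant total, which counts each variant once. CDS density is
`cds_length / (n_snvs + 1)` — exactly invertible, which the tests exploit
as an identity. Window density uses fixed non-overlapping windows anchored
at position 1 per chromosome, with mean and population SD over all windows
(empty windows included).

## Synthetic data: what it emulates, what it does not

The generators stand in for restricted inputs (reference panels of the
1000-Genomes kind, vendor raw genotypes, cohort WES). The panel simulator
is a block-copy founder model, *not* a coalescent: the genome is a chain
of LD blocks; within a block every haplotype copies one of K founder
haplotypes and then mutates (allele flips) at a small rate; ancestries
differ by Dirichlet-distributed founder weights. With K = 2 complementary
founders and no mutation, all polymorphic sites within a block are in
perfect LD and between-block LD is ≈ 0, so the fraction of off-array SNVs
an array tags is analytic from the set of covered blocks — this is what
makes the coverage-recovery tests exact. Default scale: 250 blocks × 20
SNVs (5,000 SNVs), 200 diploids of one ancestry, weight concentration 5,
mutation rate 0.002 — small enough that within-block r² stays ≫ 0.8 while
keeping sites polymorphic. These sizes keep every simulation-based test
and the end-to-end run at interactive speed; the algorithms themselves are
vectorized and scale to panels orders of magnitude larger.

The imputation-quality generator draws R² from a Beta distribution with
mean sigmoid(3.5 + 1.7·log10(MAF)) and concentration 20, so the mean falls
from ≈ 0.94 at MAF 0.4 to ≈ 0.25 at MAF 0.002, reproducing the qualitative
rare-variants-impute-worse pattern; on-array variants get R² = 1. The WES
generator flips each non-missing genotype to a different state with
probability e, so expected discordance equals e exactly. The star-allele
and catalog generators plant their truth directly (callable flags,
per-criterion failure labels) and emit it alongside the data; tests never
re-derive truth from data.

What the simulations do **not** contain: realistic demography or
recombination maps, genotyping error on the array itself, strand/build
issues, imputation-service behaviour beyond the monotone MAF link,
structural variation, and the pseudogene complexity that makes real
pharmacogenes hard. Passing tests therefore demonstrate correctness of the
metrics and recovery of planted structure, not performance claims about
any real array or population.

## Other design decisions

- Coordinates are 1-based internally (VCF convention); BED input is
  converted from 0-based half-open on read and back on write.
- Chromosome labels are normalized (leading `chr` stripped, `M` → `MT`);
  anything outside 1–22/X/Y/MT is an error, not silently carried.
- Inter-array overlap matches on (chrom, pos) only, as content overlap is
  conventionally reported; strict-allele matching is available.
- Duplicate manifest rows collapse to the first occurrence with a logged
  warning.
- Overlapping multi-allelic positions count once in overlap matrices
  (distinct positions), noted because vendors differ in how they list them.
- All generators and the pipeline are seed-deterministic; rerunning a
  config byte-identically reproduces every report table.

## Known limitations

- The excess-heterozygosity and X-chromosome QC rules are simplified (no
  sex-aware handling); sites on Y and MT are exempt from HWE.
- LD windowing assumes sorted, per-chromosome locality; r² is computed
  dense per chromosome pair-block, which is memory-quadratic per window in
  the worst case (fine at panel scales up to ~10⁵ SNVs per chromosome).
- Star-allele evaluation does not rescue strand flips or normalize indels
  beyond exact-string identity.
- `journal_if_2019` must be supplied (or joined from a journal table);
  records without it are removed by the impact-factor criterion.
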