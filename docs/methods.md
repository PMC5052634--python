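# Methods

`aseloe` detects two classes of transcriptional defect from bulk RNA-seq of
a cohort: **extreme allele-specific expression (ASE)** — one allele of a
heterozygous gene expressed at least ~7-fold above the other — and
**biallelic loss of expression (LOE)** — both alleles of a normally
high, tightly regulated gene knocked down more than 10-fold in one sample.
It also assesses two known causes of allelic imbalance, genomic imprinting
and nonsense-mediated decay (NMD), and provides a synthetic cohort
generator so the whole pipeline is testable without patient data.

## The allele model

At every heterozygous SNP passing QC, RNA-seq reads are counted per allele.
Under the null of balanced expression, the reference-allele read count at a
SNP of depth *n* is Binomial(*n*, 0.5). Reads are binned into four
categories by inheritance and expression — maternal, paternal, and (for
unphased SNPs) higher-allele and lower-allele — and summed per gene. The
four sums reduce to two directional totals H and L:

* if mat > pat:  H = higher + mat, L = lower + pat
* if pat > mat:  H = higher + pat, L = lower + mat
* tie (incl. no phase): H = higher, L = lower

The **compound allele ratio** is H/L (infinite when L = 0). The ASE P value
is the two-sided exact binomial probability 2·P(X ≥ H | n = H+L, p = 0.5),
capped at 1, Bonferroni-corrected by *m*, the number of genes with
expressed heterozygous SNPs in that sample. A gene has **extreme ASE** when
the ratio is ≥ 7.2, the corrected P is < 0.01 and the higher side carries
at least 5 reads.

Assumptions worth making explicit:

* *Unidirectional bias within a gene.* Unphased SNPs are assigned by
  putting the more-expressed base of every SNP on the same haplotype. This
  is exactly right for true monoallelic expression and anti-conservative
  for balanced genes at low depth (the higher side is selected before
  testing). The joint ratio/depth/P rule is the guard; its residual error
  is quantified on fully phased synthetic cohorts (below).
* *Pure binomial sampling.* The test assumes no overdispersion of allele
  fractions. The generator matches this by default; a beta-binomial knob
  (`overdispersion_rho`) exists for robustness studies only.
* *Two-sided tests.* Sidedness is pinned by the expression-analysis
  equivalence P < 2.7e-3 ⇔ z < −3, which is two-sided; the binomial test
  follows the same convention (the doubled tail is capped at 1).
* *Ties carry no information.* An unphased SNP with equal counts
  contributes to neither directional sum (any deterministic assignment
  would reintroduce reference bias) but still counts as an assessed SNP.
  A nonzero mat = pat tie falls back to the unknown-inheritance formula.

*m* is fixed immediately after the coverage filter, before gene-level
category filters — the earlier (larger, hence more conservative) stage.

## QC cascade

Filters run in a fixed order and only annotate/exclude, never alter
counts; each record keeps the list of filters it failed.

| filter | rule (default) |
|---|---|
| genotype quality | GQ ≥ 50 and DNA allele balance in [0.2, 0.8], bounds inclusive; missing fields (array genotypes) skipped, not failed |
| coverage | ≥ 5 reads, or both alleles expressed |
| clustered | ≥ 2 other het SNPs within ±30 bp |
| near indel | any indel within ±30 bp |
| repeat / complex allele | precomputed flags consumed, not recomputed |
| alternatively spliced exon | exon private to a strict subset of isoforms (allele-specific splicing is not ASE) |
| common biased SNP | biased in > 40% of either cohort's informative subjects, min 3; LOF variants and known-imprinted genes exempt |
| gene structure | single het SNP > 20 reads and 100% monoallelic (suspicious genotype); > 20% of the gene's SNPs unexpressed or an unexpressed coding SNP (misalignment) |
| gene categories | chrX/Y, HLA loci, noncoding, fetal-heart expression < 2 r.p.m. |
| common ASE gene | ASE in > 5% of subjects including ≥ 1 control (applied after calling) |
| subject QC | < 75% biallelic expression among SNPs with ≥ 10 reads (ignoring expected-ASE regions) excludes the subject |

A SNP-level "biased" call — needed by the common-bias and subject filters
but not defined at SNP level by the calling rule — is taken as
higher/lower ≥ 7.2 with ≥ 5 higher-allele reads, the same operating point
as the gene-level call. "Informative subjects" for the common-bias
denominator are those with a coverage-passing het genotype at that site
(a denominator over all subjects would dilute rare genotypes); a subject
biased in any tissue counts once. The known-imprinted-gene exemption is a
design choice of this package: the common-bias rule targets technical
artifacts in genes that are otherwise biallelic, whereas cohort-wide bias
at imprinted loci is the expected biology the imprinting stage assesses.

## Imprinting

Catalog genes (gene → expressed parent) with fetal-heart expression
≥ 2 r.p.m. are scored across both cohorts: a subject is informative when it
has a QC-passing het SNP in the gene, and shows ASE when the gene has an
extreme-ASE event in any tissue. A gene is classed imprinted-in-heart when
≥ 50% of informative subjects (combined cohorts by default; a per-cohort
switch exists because mixed per-cohort denominators make the membership
rule ambiguous for genes absent from one cohort) show ASE. The expressed
parent is the majority vote of trio-phased ASE subjects; conflicting votes
give "indeterminate" with a warning, and at least one phased subject is
required. Parental-origin bias is tested with the conditional two-sided
Fisher exact test (the implementation delegates to scipy; tests verify it
against exhaustive hypergeometric enumeration).

## NMD

A heterozygous LOF variant (nonsense, frameshift or canonical splice — the
three classes are pooled because all are decay-capable; the evaluable set
is configurable) shows NMD when the normal/LOF read ratio is strictly > 4
and the exact binomial P, corrected by the subject's number of het LOF
variants (not by the number of expressed genes), is < 0.01. Direction
matters: over-expression *of* the LOF allele is never NMD. The LOF allele
is the ALT base, since effect annotations describe the alternate allele.

## Expression analysis

Expression is quantified as reads per gene per million aligned reads
(r.p.m.); a gene is expressed at ≥ 2 r.p.m. Each sample is compared with
all other samples of the same tissue type (groups need > 4 samples): fold
= sample / leave-one-out mean, z = (sample − mean)/sd with the n−1 sample
estimator (the estimator choice is asserted in tests; printed-table
reproductions tolerate rounding), P = two-sided normal tail. Derived
thresholds are computed in code, not hard-coded:

* downregulated ASE: fold < 0.5 + 0.5·0.3 = 0.65 with P < 0.05
  (allele loss halves expression; 30% relaxation for cohort heterogeneity);
* upregulated ASE: fold > 5 with P < 0.05 (7.2-fold gain relaxed by 30%);
* LOE: fold < 0.1 with P < 2·Φ(−3) = 2.6998e-3.

Samples with > 100 strong expression differences (fold < 0.2 or > 5 at
P < 0.05) are excluded as degraded. LOE candidacy requires the gene to be
highly expressed (leave-one-out mean in the upper quartile of the tissue
group's expressed genes — the cell's own knockdown must not disqualify its
gene, hence the leave-one-out mean) and tightly regulated. "Tightly
regulated" has no published definition; this package uses a leave-one-out
coefficient of variation ≤ 0.5 (configurable) and flags it as a modelling
choice. Calls are restricted to polyadenylated transcripts. Length-
normalised r.p.k.m. can be derived from the gene models but plays no role
in any call. Cohort burdens (subjects with expression-changed ASE, subjects
with LOE) are compared case vs control by Fisher exact test with explicit
denominators supplied by the caller, since published burden denominators
(subjects vs tissues, pre/post QC) are not always recoverable.

## Synthetic cohorts

`SimulationConfig`/`generate_cohort` produce genotypes (per-subject VCFs,
trio-phased "1|0"/"0|1" for a configurable fraction of subjects, maternal
allele written first), allele counts (binomial at the configured fraction),
a gene × sample expression matrix, a fetal-heart reference and full truth
labels. Default scale is 200 genes × 24 subjects (12 cases, 12 controls)
× 2 tissues at mean depth 60 per SNP — small enough that the full pipeline
runs in seconds, large enough that every cohort-level filter has work to
do. Design features:

* Candidate SNP sites are fixed per gene and shared across subjects
  (each subject heterozygous per site with the probability implied by the
  SNPs-per-gene mean), so cross-subject filters see recurrent sites.
* Within a gene, event SNPs place the over-expressed base on one haplotype
  — the assumption the phasing heuristic exploits; null SNPs randomise
  which base is higher. Haplotype 1 is maternal for phased subjects.
* Expression is log-normal around a gene-specific mean (log-mean 3.4,
  log-sd 1.2 in r.p.m.) with gene × tissue structure (log-sd 0.15) and
  within-group noise CV 0.2, so leave-one-out z-scores are meaningful.
* Injected events: extreme ASE at allele fraction 0.95 (near-monoallelic,
  the regime extreme-ASE discovery targets; an optional expression fold
  couples an event to total-expression change — 0.5 for uncompensated
  allele loss, 1.0 for dosage compensation), imprinting with per-subject
  penetrance, NMD with the LOF haplotype at 10% of reads plus configured
  expressed-LOF backgrounds that populate the NMD denominator, and LOE at
  fold 0.05 on upper-quartile genes (the severe regime such events show).
* Mapping-bias contamination forces selected genotype records to
  monoallelic reference expression and gives them positional QC flags with
  configurable probability. The default contamination rate of the
  study-scale cohort (4% of records) puts the pre-QC reference-base share
  among biased SNPs near the ~87% seen in uncorrected allele counts; after
  the cascade the share returns to ~50%.
* `subsample_snps` thins genotypes to every k-th SNP per subject in
  genomic order, emulating the density reduction used when comparing
  F1-hybrid-scale SNP sets to human WGS.

What the generator does **not** emulate: alignment artifacts at base level
(contamination is injected at the count level), realistic splice structure
(isoform membership is a flag), linkage between SNPs beyond shared
haplotypes, overdispersed allele counts (off by default), and
depth heterogeneity across genes. Passing tests therefore demonstrate the
statistical machinery and filter logic under the model's own assumptions,
not robustness to every artifact of real sequencing data. The read-depth
distribution at het SNPs is unpublished; the default (Poisson, mean 60) is
chosen for test power, not fidelity.

## Phasing validation

`evaluate_phasing_grid` quantifies the higher-allele heuristic on fully
phased cohorts (`f1_validation_config`: strong events at fraction 0.93
plus weak imbalance at 0.62–0.70, mean depth 15, ~2 SNPs/gene). At each
(minimum ratio, minimum per-SNP depth) grid point, genes are called with
and without phase from the same records; an unphased call not reproduced
by phased calling is a false assignment. Pooled over cohorts, the
(7.2, 5) operating point mis-assigns well under 2% of calls and false-call
counts fall as either parameter tightens. Note that the false *rate* is
monotone only up to small-count discreteness: tightening a threshold can
remove true calls faster than false calls, nudging the ratio up by ~1e-4
while the counts fall; tests allow that much.

## Numerical and degenerate-input choices

* Binomial and normal tails come from scipy (`binom.sf`, `norm.sf`);
  exact enumeration oracles in the test suite pin them to 1e-12 for
  n ≤ 200 and verify the Fisher test against hypergeometric enumeration.
* H + L = 0 genes are skipped (the test is undefined); a leave-one-out
  mean of 0 gives an undefined fold and the cell is skipped, likewise a
  zero sd for z.
* Infinite allele ratios (L = 0) pass the ≥ 7.2 threshold when the higher
  side has ≥ 5 reads.
* Integer percentages use Python's round (banker's at .5).
* All randomness flows through `numpy.random.default_rng` seeded from the
  config; identical config ⇒ byte-identical outputs, and every output TSV
  header records the package version, config hash and seed.

## Known limitations

* The unphased statistic is anti-conservative by construction at low
  depth; the calibration tests document (not remove) this.
* Imprinting penetrance, NMD efficiency and contamination structure are
  simplifications; real cohorts mix genotyping platforms with very
  different SNP densities, which this generator does not model.
* The common-bias subject pooling across tissues (a subject counts once if
  biased in any tissue) is a reading the published rule leaves open.
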