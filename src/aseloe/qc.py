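"""Subject-, SNP- and gene-level quality control preceding ASE calling.

The cascade runs in a fixed, logged order and never modifies read counts:
filters only annotate records with the names of the filters they failed and
exclude them from downstream analysis. Every SNP/gene therefore carries a
full audit trail of why it was removed.

Filter order:

1.  genotype quality (GQ >= 50, DNA allele balance in [0.2, 0.8]);
2.  RNA coverage (>= 5 reads, or both alleles expressed);
3.  positional artifacts (clustered SNPs, SNPs near indels, repeat flags);
4.  alternatively spliced exons (allele-specific splicing is not ASE);
5.  complex-allele flag (more than two alleles observed upstream);
6.  cohort-wide common-biased SNPs (biased in >40% of either cohort's
    informative subjects, minimum three, LOF variants exempt);
7.  gene structure per sample (single high-coverage monoallelic SNP;
    misaligned-read pattern);
8.  gene categories (chrX/Y, HLA, noncoding, low fetal-heart expression);
9.  subject-level biallelic fraction (subjects with <75% biallelic
    expression among well-covered SNPs are dropped).

A SNP-level "biased" call — used by the common-bias and subject filters —
is a higher/lower read ratio >= 7.2 with at least 5 reads on the higher
allele, the same operating point as the gene-level extreme-ASE call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from aseloe.io import EXPRESSED_RPM_MIN, LOF_EFFECT_CLASSES, GeneModel

__all__ = [
    "QCConfig", "FilterOutcome", "QCResult",
    "filter_genotype_quality", "filter_min_coverage", "filter_positional",
    "flag_biased_snp", "biased_mask", "filter_common_biased_snps",
    "filter_gene_structure", "filter_gene_categories",
    "filter_common_ase_genes", "subject_biallelic_fraction",
    "run_qc", "HLA_GENES",
]

log = logging.getLogger("aseloe.qc")

#: HLA loci excluded from ASE analysis (classical and non-classical).
HLA_GENES = frozenset({
    "HLA-A", "HLA-B", "HLA-C", "HLA-DMA", "HLA-DMB", "HLA-DOA", "HLA-DOB",
    "HLA-DPA1", "HLA-DPB1", "HLA-DQA1", "HLA-DQA2", "HLA-DQB1", "HLA-DQB2",
    "HLA-DRA", "HLA-DRB1", "HLA-DRB5", "HLA-E", "HLA-F", "HLA-G", "HLA-J",
    "HLA-P", "HLA-T",
})


@dataclass(frozen=True)
class QCConfig:
    """Thresholds of the filter cascade (defaults are the operating points)."""

    min_gq: float = 50.0
    ab_low: float = 0.2
    ab_high: float = 0.8
    min_snp_reads: int = 5
    cluster_window_bp: int = 30
    cluster_min_neighbors: int = 2
    indel_window_bp: int = 30
    bias_ratio: float = 7.2
    bias_min_reads: int = 5
    common_bias_subject_fraction: float = 0.40
    common_bias_min_subjects: int = 3
    single_snp_high_reads: int = 20
    unexpressed_fraction: float = 0.20
    fetal_rpm_min: float = EXPRESSED_RPM_MIN
    common_ase_subject_fraction: float = 0.05
    subject_biallelic_min: float = 0.75
    subject_biallelic_min_reads: int = 10

    def __post_init__(self):
        for name in ("min_gq", "min_snp_reads", "cluster_window_bp", "indel_window_bp",
                     "bias_ratio", "bias_min_reads", "common_bias_min_subjects",
                     "single_snp_high_reads", "fetal_rpm_min",
                     "subject_biallelic_min_reads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("ab_low", "ab_high", "common_bias_subject_fraction",
                     "unexpressed_fraction", "common_ase_subject_fraction",
                     "subject_biallelic_min"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0,1), got {v}")


@dataclass(frozen=True)
class FilterOutcome:
    """Audit record: what failed and why, for one SNP or gene key."""

    key: tuple
    verdict: str  # "pass" / "fail"
    failed_filters: tuple = ()

    def __post_init__(self):
        if (self.verdict == "fail") != bool(self.failed_filters):
            raise ValueError("verdict fail iff failed_filters non-empty")


# ---------------------------------------------------------------------------
# SNP-level filters (each returns a fail mask aligned to the input frame)
# ---------------------------------------------------------------------------

def filter_genotype_quality(df: pd.DataFrame, cfg: QCConfig = QCConfig()) -> pd.Series:
    """Fail GQ < 50 or DNA allele balance outside [0.2, 0.8] (bounds pass).

    Records with missing GQ/AB — array-genotyped subjects carry neither —
    are skipped with a logged note rather than failed.
    """
    gq, ab = df["gq"], df["dna_ab"]
    n_missing = int((gq.isna() | ab.isna()).sum())
    if n_missing:
        log.info("genotype-quality filter skipped %d records with missing GQ/AB", n_missing)
    fail = (gq < cfg.min_gq) | (ab < cfg.ab_low) | (ab > cfg.ab_high)
    return fail.fillna(False)


def filter_min_coverage(df: pd.DataFrame, cfg: QCConfig = QCConfig()) -> pd.Series:
    """Pass with >= 5 total reads, or with both alleles expressed."""
    total = df["ref_reads"] + df["alt_reads"]
    ok = (total >= cfg.min_snp_reads) | ((df["ref_reads"] >= 1) & (df["alt_reads"] >= 1))
    return ~ok


def _clustered(positions: np.ndarray, window: int, min_neighbors: int) -> np.ndarray:
    pos = np.sort(positions)
    lo = np.searchsorted(pos, pos - window, side="left")
    hi = np.searchsorted(pos, pos + window, side="right")
    neighbors = hi - lo - 1
    fail_sorted = neighbors >= min_neighbors
    out = np.empty(len(positions), dtype=bool)
    out[np.argsort(positions, kind="stable")] = fail_sorted
    return out


def filter_positional(
    df: pd.DataFrame,
    indels: pd.DataFrame | None = None,
    cfg: QCConfig = QCConfig(),
) -> pd.DataFrame:
    """Positional artifact filters; returns fail masks per reason.

    ``clustered``: >= 2 other het SNPs of the same subject within +/-30 bp
    (or the precomputed flag); ``near_indel``: any indel within +/-30 bp of
    the SNP (or the flag); ``repeat_region``: the precomputed repeat flag —
    recomputing paralogous alignments is upstream of this package.
    """
    clustered = df.get("flag_clustered", pd.Series(False, index=df.index)).copy().astype(bool)
    sites = df[["subject_id", "chrom", "pos"]].drop_duplicates()
    for (subject, chrom), sub in sites.groupby(["subject_id", "chrom"], sort=False):
        mask = _clustered(sub["pos"].to_numpy(), cfg.cluster_window_bp, cfg.cluster_min_neighbors)
        bad = set(sub["pos"].to_numpy()[mask])
        if bad:
            sel = (df["subject_id"] == subject) & (df["chrom"] == chrom) & df["pos"].isin(bad)
            clustered |= sel
    near_indel = df.get("flag_near_indel", pd.Series(False, index=df.index)).copy().astype(bool)
    if indels is not None and len(indels):
        for (subject, chrom), sub in indels.groupby(["subject_id", "chrom"], sort=False):
            ipos = np.sort(sub["pos"].to_numpy())
            sel = (df["subject_id"] == subject) & (df["chrom"] == chrom)
            pos = df.loc[sel, "pos"].to_numpy()
            lo = np.searchsorted(ipos, pos - cfg.indel_window_bp, side="left")
            hi = np.searchsorted(ipos, pos + cfg.indel_window_bp, side="right")
            near_indel.loc[sel] |= (hi - lo) > 0
    repeat = df.get("flag_repeat_region", pd.Series(False, index=df.index)).astype(bool)
    return pd.DataFrame({"clustered": clustered, "near_indel": near_indel,
                         "repeat_region": repeat})


def flag_biased_snp(ref_reads: int, alt_reads: int, cfg: QCConfig = QCConfig()) -> bool:
    """SNP-level bias: higher/lower ratio >= 7.2 with >= 5 higher-allele reads."""
    higher, lower = max(ref_reads, alt_reads), min(ref_reads, alt_reads)
    if higher < cfg.bias_min_reads:
        return False
    return lower == 0 or higher / lower >= cfg.bias_ratio


def biased_mask(df: pd.DataFrame, cfg: QCConfig = QCConfig()) -> pd.Series:
    """Vectorised :func:`flag_biased_snp` over a counts frame."""
    higher = df[["ref_reads", "alt_reads"]].max(axis=1)
    lower = df[["ref_reads", "alt_reads"]].min(axis=1)
    with np.errstate(divide="ignore"):
        ratio = np.where(lower > 0, higher / lower.replace(0, np.nan), np.inf)
    return pd.Series((higher >= cfg.bias_min_reads) & (ratio >= cfg.bias_ratio), index=df.index)


def filter_common_biased_snps(
    df: pd.DataFrame,
    cohort_of: Mapping[str, str],
    cfg: QCConfig = QCConfig(),
    exempt_genes: Iterable[str] = (),
) -> pd.Series:
    """Fail sites biased in >40% (min 3) of either cohort's informative subjects.

    Informative subjects for a site are those with a coverage-passing het
    genotype; a subject counts as biased if biased in any tissue. SNPs whose
    effect class is LOF (nonsense/frameshift/splice) are exempt — their bias
    may be genuine nonsense-mediated decay — as are SNPs in ``exempt_genes``
    (known imprinted genes, where cohort-wide bias is expected biology
    rather than a technical artifact).
    """
    work = df.copy()
    work["cohort"] = work["subject_id"].map(cohort_of)
    work["biased"] = biased_mask(work, cfg)
    per_subject = (
        work.groupby(["chrom", "pos", "ref", "alt", "cohort", "subject_id"], sort=False)["biased"]
        .any().reset_index()
    )
    stats = (
        per_subject.groupby(["chrom", "pos", "ref", "alt", "cohort"], sort=False)["biased"]
        .agg(n_biased="sum", n_informative="count").reset_index()
    )
    stats["common"] = (
        (stats["n_biased"] / stats["n_informative"] > cfg.common_bias_subject_fraction)
        & (stats["n_biased"] >= cfg.common_bias_min_subjects)
    )
    bad_sites = set(map(tuple, stats.loc[stats["common"], ["chrom", "pos", "ref", "alt"]].to_numpy()))
    keys = list(map(tuple, df[["chrom", "pos", "ref", "alt"]].to_numpy()))
    fail = pd.Series([k in bad_sites for k in keys], index=df.index)
    exempt = df["effect_class"].isin(LOF_EFFECT_CLASSES) | df["gene_id"].isin(set(exempt_genes))
    return fail & ~exempt


# ---------------------------------------------------------------------------
# gene-level filters
# ---------------------------------------------------------------------------

def alt_spliced_mask(df: pd.DataFrame, gene_models: Iterable[GeneModel]) -> pd.Series:
    """SNPs in exons private to a strict subset of the gene's isoforms."""
    models = {g.gene_id: g for g in gene_models}
    out = np.zeros(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        g = models.get(row.gene_id)
        if g is None:
            continue
        exon = g.exon_at(int(row.pos))
        if exon is not None and set(exon[2]) < set(g.all_isoforms):
            out[i] = True
    mask = pd.Series(out, index=df.index)
    if "flag_alt_spliced_exon" in df.columns:
        mask |= df["flag_alt_spliced_exon"].astype(bool)
    return mask


def filter_gene_structure(
    df: pd.DataFrame,
    gene_models: Iterable[GeneModel],
    cfg: QCConfig = QCConfig(),
) -> pd.Series:
    """Per-sample gene exclusions driven by suspicious SNP expression patterns.

    A gene in a sample fails ``single_snp_monoallelic`` when its only het
    SNP has >20 reads all on one allele (a suspicious genotype), and fails
    ``misaligned`` when >20% of its het SNPs are unexpressed or any coding
    het SNP is unexpressed — patterns produced by misaligned reads rather
    than ASE. Returns per-row fail masks (one column per reason); all the
    gene's rows in that sample fail together.
    """
    coding = {g.gene_id: g.coding_flag for g in gene_models}
    total = df["ref_reads"] + df["alt_reads"]
    mono = ((df["ref_reads"] == 0) | (df["alt_reads"] == 0)) & (total > cfg.single_snp_high_reads)
    unexpressed = total == 0
    coding_unexpressed = unexpressed & df["effect_class"].isin(
        ["synonymous", "missense", "nonsense"]) & df["gene_id"].map(coding).fillna(True)

    grp = df.groupby(["subject_id", "tissue", "gene_id"], sort=False)
    n_snps = grp["pos"].transform("count")
    single_fail = (n_snps == 1) & mono
    unexp_count = unexpressed.groupby(
        [df["subject_id"], df["tissue"], df["gene_id"]]).transform("sum")
    misaligned = (unexp_count / n_snps > cfg.unexpressed_fraction) & (n_snps > 1)
    misaligned |= coding_unexpressed.groupby(
        [df["subject_id"], df["tissue"], df["gene_id"]]).transform("any")
    single_fail = single_fail.groupby(
        [df["subject_id"], df["tissue"], df["gene_id"]]).transform("any")
    return pd.DataFrame({"single_snp_monoallelic": single_fail, "misaligned": misaligned})


def filter_gene_categories(
    gene_models: Iterable[GeneModel],
    fetal_reference: pd.Series,
    cfg: QCConfig = QCConfig(),
) -> pd.DataFrame:
    """Static gene exclusions: sex chromosomes, HLA, noncoding, low fetal r.p.m.

    Returns a frame indexed by gene id with boolean fail columns; a fetal
    r.p.m. exactly at the threshold passes ("<2 r.p.m." fails).
    """
    rows = {}
    for g in gene_models:
        fetal = float(fetal_reference.get(g.gene_id, np.nan))
        rows[g.gene_id] = {
            "sex_chromosome": g.chrom in ("chrX", "chrY", "X", "Y"),
            "hla": g.is_hla or g.gene_symbol in HLA_GENES,
            "noncoding": not g.coding_flag,
            "low_fetal_expression": (fetal == fetal) and fetal < cfg.fetal_rpm_min,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene_id"
    out["fail"] = out.any(axis=1)
    return out


def filter_common_ase_genes(
    ase_subjects: Mapping[str, Iterable[str]],
    n_subjects_total: int,
    cohort_of: Mapping[str, str],
    cfg: QCConfig = QCConfig(),
) -> set:
    """Genes with ASE in >5% of all subjects including >= 1 control subject.

    Applied after calling, on the cohort-wide tally of subjects with an
    extreme-ASE event per gene.
    """
    common = set()
    for gene, subs in ase_subjects.items():
        subs = set(subs)
        frac = len(subs) / n_subjects_total
        has_control = any(cohort_of.get(s) == "control" for s in subs)
        if frac > cfg.common_ase_subject_fraction and has_control:
            common.add(gene)
    return common


def subject_biallelic_fraction(
    df: pd.DataFrame,
    gene_models: Iterable[GeneModel],
    cfg: QCConfig = QCConfig(),
) -> pd.DataFrame:
    """Fraction of well-covered SNPs expressed biallelically, per subject.

    Qualifying SNPs have >= 10 reads and sit outside the regions where ASE
    is expected (chrX, known-imprinted genes, alternatively spliced exons).
    Subjects below 75% biallelic are excluded.
    """
    imprinted = {g.gene_id for g in gene_models if g.known_imprinted}
    total = df["ref_reads"] + df["alt_reads"]
    qualifying = (
        (total >= cfg.subject_biallelic_min_reads)
        & ~df["chrom"].isin(("chrX", "X"))
        & ~df["gene_id"].isin(imprinted)
        & ~df.get("flag_alt_spliced_exon", pd.Series(False, index=df.index)).astype(bool)
    )
    sub = df[qualifying].copy()
    sub["biallelic"] = ~biased_mask(sub, cfg)
    out = sub.groupby("subject_id")["biallelic"].agg(fraction="mean", n_snps="count").reset_index()
    out["verdict"] = np.where(out["fraction"] >= cfg.subject_biallelic_min, "keep", "exclude")
    return out


# ---------------------------------------------------------------------------
# cascade orchestration
# ---------------------------------------------------------------------------

@dataclass
class QCResult:
    """Filtered records plus the audit trail of the cascade."""

    passed: pd.DataFrame            # SNP x sample records surviving all filters
    records: pd.DataFrame           # all records with failed_filters column
    gene_fails: pd.DataFrame        # static gene-category outcomes
    subject_qc: pd.DataFrame        # per-subject biallelic fraction and verdict
    attrition: pd.DataFrame         # records removed per filter per cohort
    m_per_sample: pd.Series         # Bonferroni divisor per (subject, tissue)
    filter_order: tuple = ()

    def outcomes(self) -> list[FilterOutcome]:
        out = []
        for row in self.records.itertuples(index=False):
            failed = tuple(f for f in row.failed_filters.split(",") if f)
            key = (row.subject_id, row.tissue, row.chrom, row.pos)
            out.append(FilterOutcome(key=key, verdict="fail" if failed else "pass",
                                     failed_filters=failed))
        return out


FILTER_ORDER = (
    "genotype_quality", "min_coverage", "clustered", "near_indel",
    "repeat_region", "alt_spliced", "complex_allele", "common_biased",
    "single_snp_monoallelic", "misaligned", "gene_category", "subject_excluded",
)


def run_qc(
    snps: pd.DataFrame,
    counts: pd.DataFrame,
    gene_models: Iterable[GeneModel],
    fetal_reference: pd.Series,
    cohort_of: Mapping[str, str],
    indels: pd.DataFrame | None = None,
    cfg: QCConfig = QCConfig(),
) -> QCResult:
    """Run the full cascade in order and return the audit trail.

    ``snps`` and ``counts`` are joined on (subject, chrom, pos); the merged
    records are annotated with every filter they fail, in cascade order.
    The Bonferroni divisor ``m`` per sample — the number of genes with at
    least one coverage-passing het SNP — is computed right after the
    coverage filter, before any gene-level category filter, which is the
    conservative stage.
    """
    gene_models = list(gene_models)
    df = counts.merge(snps, on=["subject_id", "chrom", "pos", "ref", "alt"], how="inner")
    if len(df) < len(counts):
        log.info("run_qc: %d count records had no matching genotype", len(counts) - len(df))
    fails: dict[str, pd.Series] = {}

    fails["genotype_quality"] = filter_genotype_quality(df, cfg)
    fails["min_coverage"] = filter_min_coverage(df, cfg)
    positional = filter_positional(df, indels=indels, cfg=cfg)
    fails["clustered"] = positional["clustered"]
    fails["near_indel"] = positional["near_indel"]
    fails["repeat_region"] = positional["repeat_region"]
    fails["alt_spliced"] = alt_spliced_mask(df, gene_models)
    fails["complex_allele"] = df.get(
        "flag_complex_allele", pd.Series(False, index=df.index)).astype(bool)

    # m is fixed here: genes with >=1 coverage-passing het SNP per sample
    cov_ok = df[~fails["min_coverage"] & ~fails["genotype_quality"]]
    m_per_sample = cov_ok.groupby(["subject_id", "tissue"])["gene_id"].nunique()
    m_per_sample.name = "m"

    imprinted_genes = {g.gene_id for g in gene_models if g.known_imprinted}
    pre_common = ~pd.concat(fails, axis=1).any(axis=1)
    fails["common_biased"] = filter_common_biased_snps(
        df[pre_common], cohort_of, cfg, exempt_genes=imprinted_genes,
    ).reindex(df.index, fill_value=False)

    surviving = ~pd.concat(fails, axis=1).any(axis=1)
    structure = filter_gene_structure(df[surviving], gene_models, cfg).reindex(
        df.index, fill_value=False)
    fails["single_snp_monoallelic"] = structure["single_snp_monoallelic"]
    fails["misaligned"] = structure["misaligned"]

    gene_fails = filter_gene_categories(gene_models, fetal_reference, cfg)
    fails["gene_category"] = df["gene_id"].map(gene_fails["fail"]).fillna(False).astype(bool)

    surviving = ~pd.concat(fails, axis=1).any(axis=1)
    subject_qc = subject_biallelic_fraction(df[surviving], gene_models, cfg)
    excluded = set(subject_qc.loc[subject_qc["verdict"] == "exclude", "subject_id"])
    fails["subject_excluded"] = df["subject_id"].isin(excluded)

    fail_frame = pd.concat(fails, axis=1)[list(FILTER_ORDER)]
    records = df.copy()
    records["failed_filters"] = [
        ",".join(name for name, hit in zip(FILTER_ORDER, row) if hit)
        for row in fail_frame.to_numpy()
    ]
    passed = records[records["failed_filters"] == ""].drop(columns="failed_filters")

    cohort = df["subject_id"].map(cohort_of).fillna("case")
    attrition = (
        fail_frame.groupby(cohort.to_numpy()).sum().T
        .rename_axis("filter").reset_index()
    )
    log.info("QC cascade order: %s", " -> ".join(FILTER_ORDER))
    return QCResult(
        passed=passed.reset_index(drop=True), records=records,
        gene_fails=gene_fails, subject_qc=subject_qc, attrition=attrition,
        m_per_sample=m_per_sample, filter_order=FILTER_ORDER,
    )
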