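"""Readers/writers and canonical in-memory records.

Conventions used throughout the package:

* coordinates are 1-based and fully closed, as in VCF;
* allele counts are always reported in reference orientation — gene strand
  never flips allele identity;
* all joins between genotype and count tables are on
  ``(subject_id, chrom, pos)`` with ``(ref, alt)`` checked on read;
* tabular outputs are TSV with ``#``-prefixed header comments recording the
  package version, a config hash and the seed, so every artifact is
  traceable to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EXPRESSED_RPM_MIN",
    "LOF_EFFECT_CLASSES",
    "HetSNP",
    "AlleleCount",
    "GeneModel",
    "ExpressionTable",
    "read_het_vcf",
    "write_het_vcf",
    "read_allele_counts",
    "write_allele_counts",
    "read_gene_models",
    "write_gene_models",
    "read_imprint_catalog",
    "write_imprint_catalog",
    "read_fetal_reference",
    "write_fetal_reference",
    "compute_rpm",
    "read_expression",
    "write_expression",
    "snps_to_frame",
    "frame_to_snps",
    "header_lines",
    "write_tsv",
    "read_tsv",
    "config_hash",
]

log = logging.getLogger("aseloe")

#: a gene counts as expressed at or above this many reads per million.
EXPRESSED_RPM_MIN = 2.0

#: annotation classes treated as loss-of-function (NMD-capable).
LOF_EFFECT_CLASSES = frozenset({"nonsense", "frameshift", "splice"})

SNP_FLAGS = ("clustered", "near_indel", "repeat_region", "alt_spliced_exon", "complex_allele")

PARENT_LABELS = ("maternal", "paternal", "unknown")


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HetSNP:
    """One heterozygous site in one subject, with genotype QC fields.

    ``parental_origin_of_alt`` records which parental haplotype carries the
    ALT base ("maternal", "paternal" or "unknown"); ``dna_allele_balance``
    is ALT/(REF+ALT) read support in the genomic DNA sequencing and is NaN
    for array-genotyped subjects, whose VCFs carry no read depths.
    """

    subject_id: str
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    genotype_quality: float = float("nan")
    dna_allele_balance: float = float("nan")
    parental_origin_of_alt: str = "unknown"
    effect_class: str = "unknown"
    population_af: float = float("nan")
    gene_id: str = ""
    flags: frozenset = frozenset()

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >=1, got {self.pos}")
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base and alt_base must differ")
        if self.parental_origin_of_alt not in PARENT_LABELS:
            raise ValueError(f"bad parental origin {self.parental_origin_of_alt!r}")
        ab = self.dna_allele_balance
        if ab == ab and not (0.0 <= ab <= 1.0):  # NaN-safe
            raise ValueError(f"dna_allele_balance outside [0,1]: {ab}")


@dataclass(frozen=True)
class AlleleCount:
    """RNA-seq read support for each allele of one het SNP in one sample."""

    subject_id: str
    tissue: str
    chrom: str
    pos: int
    ref_reads: int
    alt_reads: int

    def __post_init__(self):
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")


@dataclass(frozen=True)
class GeneModel:
    """Gene annotation: exon/isoform structure plus category flags."""

    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    #: (start, end, isoform_ids) with 1-based closed intervals
    exons: tuple = ()
    coding_flag: bool = True
    is_hla: bool = False
    known_imprinted: str | None = None  # "maternal" / "paternal" / None
    polyadenylated: bool = True

    def __post_init__(self):
        for start, end, isoforms in self.exons:
            if not start < end:
                raise ValueError(f"{self.gene_id}: bad exon interval ({start},{end})")
            if not isoforms:
                raise ValueError(f"{self.gene_id}: exon without isoform membership")

    @property
    def all_isoforms(self) -> frozenset:
        out: set = set()
        for _, _, isoforms in self.exons:
            out.update(isoforms)
        return frozenset(out)

    def exon_at(self, pos: int):
        for exon in self.exons:
            if exon[0] <= pos <= exon[1]:
                return exon
        return None


@dataclass
class ExpressionTable:
    """Per-gene read counts and r.p.m. per sample, with sample metadata.

    ``counts`` is genes x samples; ``samples`` is indexed by sample id with
    columns subject_id, tissue, total_aligned_reads. ``rpm`` holds
    counts * 1e6 / total_aligned_reads, the expression unit used everywhere.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    rpm: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        missing = {"subject_id", "tissue", "total_aligned_reads"} - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample table missing columns: {sorted(missing)}")
        totals = self.samples["total_aligned_reads"].astype(float)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0][0]
            raise ValueError(f"total_aligned_reads must be positive (sample {bad})")
        if list(self.counts.columns) != list(self.samples.index):
            self.counts = self.counts.reindex(columns=self.samples.index)
        if self.rpm is None:
            self.rpm = self.counts * 1e6 / totals

    def expressed(self) -> pd.DataFrame:
        """Boolean genes x samples mask: r.p.m. at or above the expressed cut."""
        return self.rpm >= EXPRESSED_RPM_MIN


# ---------------------------------------------------------------------------
# frame conversions
# ---------------------------------------------------------------------------

SNP_COLUMNS = [
    "subject_id", "chrom", "pos", "ref", "alt", "gene_id", "gq", "dna_ab",
    "parental_origin", "effect_class", "population_af",
] + [f"flag_{f}" for f in SNP_FLAGS]


def snps_to_frame(snps: Iterable[HetSNP]) -> pd.DataFrame:
    rows = []
    for s in snps:
        row = {
            "subject_id": s.subject_id, "chrom": s.chrom, "pos": s.pos,
            "ref": s.ref_base, "alt": s.alt_base, "gene_id": s.gene_id,
            "gq": s.genotype_quality, "dna_ab": s.dna_allele_balance,
            "parental_origin": s.parental_origin_of_alt,
            "effect_class": s.effect_class, "population_af": s.population_af,
        }
        for f in SNP_FLAGS:
            row[f"flag_{f}"] = f in s.flags
        rows.append(row)
    df = pd.DataFrame(rows, columns=SNP_COLUMNS)
    df["pos"] = df["pos"].astype(int)
    return df


def frame_to_snps(df: pd.DataFrame) -> list[HetSNP]:
    out = []
    for row in df.itertuples(index=False):
        flags = frozenset(f for f in SNP_FLAGS if getattr(row, f"flag_{f}", False))
        out.append(HetSNP(
            subject_id=row.subject_id, chrom=row.chrom, pos=int(row.pos),
            ref_base=row.ref, alt_base=row.alt, gene_id=row.gene_id,
            genotype_quality=float(row.gq), dna_allele_balance=float(row.dna_ab),
            parental_origin_of_alt=row.parental_origin,
            effect_class=row.effect_class, population_af=float(row.population_af),
            flags=flags,
        ))
    return out


# ---------------------------------------------------------------------------
# provenance headers
# ---------------------------------------------------------------------------

def config_hash(obj) -> str:
    """Stable short hash of any JSON-serialisable config object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def header_lines(seed=None, cfg_hash: str | None = None) -> list[str]:
    from aseloe import __version__

    lines = [f"# aseloe version={__version__}"]
    if cfg_hash is not None:
        lines.append(f"# config_hash={cfg_hash}")
    if seed is not None:
        lines.append(f"# seed={seed}")
    return lines


def write_tsv(df: pd.DataFrame, path, seed=None, cfg_hash=None, index=False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines(seed=seed, cfg_hash=cfg_hash):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

def _parent_alt_counts(path) -> dict:
    """Map (chrom, pos, ref, alt) -> ALT allele count (0/1/2) for one parent."""
    from cyvcf2 import VCF

    out = {}
    vcf = VCF(str(path))
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        gt = v.gt_types[0]  # 0=hom-ref 1=het 2=unknown 3=hom-alt
        alt_n = {0: 0, 1: 1, 3: 2}.get(int(gt))
        if alt_n is not None:
            out[(v.CHROM, v.POS, v.REF, v.ALT[0])] = alt_n
    vcf.close()
    return out


def _origin_from_trio(mom: int | None, dad: int | None) -> str:
    """Parental origin of the ALT base in a het child, from parent ALT counts."""
    if mom is None or dad is None:
        return "unknown"
    if mom == 2:
        return "maternal"
    if dad == 2:
        return "paternal"
    if mom >= 1 and dad == 0:
        return "maternal"
    if dad >= 1 and mom == 0:
        return "paternal"
    return "unknown"  # both het (ambiguous) or Mendelian inconsistency


def read_het_vcf(path, trio_paths: Mapping[str, str] | None = None) -> list[HetSNP]:
    """Read biallelic heterozygous SNPs for one subject from a VCF.

    Parental origin of the ALT base is set from a phased GT (left allele is
    maternal, the trio-phasing convention this package writes) or, for
    unphased genotypes, from Mendelian transmission in the optional trio
    VCFs (``trio_paths`` maps "mother"/"father" to paths); ambiguous sites
    stay "unknown". Multi-allelic sites are skipped with a logged count;
    homozygous sites are ignored.
    """
    from cyvcf2 import VCF

    mom = _parent_alt_counts(trio_paths["mother"]) if trio_paths else None
    dad = _parent_alt_counts(trio_paths["father"]) if trio_paths else None

    vcf = VCF(str(path))
    if len(vcf.samples) != 1:
        raise ValueError(f"{path}: expected a single-sample VCF, got {vcf.samples}")
    subject = vcf.samples[0]
    out: list[HetSNP] = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if int(v.gt_types[0]) != 1:  # keep only het calls
            continue
        gq = float(v.gt_quals[0]) if v.gt_quals is not None else float("nan")
        ab = float("nan")
        ad = v.format("AD")
        if ad is not None:
            ref_d, alt_d = float(ad[0][0]), float(ad[0][1])
            if ref_d >= 0 and alt_d >= 0 and ref_d + alt_d > 0:
                ab = alt_d / (ref_d + alt_d)
        origin = "unknown"
        phases = v.gt_phases
        if phases is not None and bool(phases[0]):
            # left allele of x|y is maternal by convention
            a0 = v.genotypes[0][0]
            origin = "maternal" if a0 == 1 else "paternal"
        elif mom is not None:
            key = (v.CHROM, v.POS, v.REF, v.ALT[0])
            origin = _origin_from_trio(mom.get(key), dad.get(key))  # type: ignore[union-attr]
        info = dict(v.INFO)
        flag_str = info.get("FLAGS", "") or ""
        flags = frozenset(f for f in str(flag_str).split(",") if f in SNP_FLAGS)
        out.append(HetSNP(
            subject_id=subject, chrom=v.CHROM, pos=v.POS,
            ref_base=v.REF, alt_base=v.ALT[0],
            genotype_quality=gq, dna_allele_balance=ab,
            parental_origin_of_alt=origin,
            effect_class=str(info.get("EFFECT", "unknown")),
            population_af=float(info.get("MAF", "nan")),
            gene_id=str(info.get("GENE", "")),
            flags=flags,
        ))
    vcf.close()
    if n_multi:
        log.info("%s: skipped %d multi-allelic sites", path, n_multi)
    return out


def write_het_vcf(snps: Sequence[HetSNP], path, seed=None) -> None:
    """Write one subject's het SNPs as a minimal VCF 4.2 file.

    Subjects with known parental origin get phased GTs (maternal allele
    first: "1|0" when the ALT is maternal); others get unphased "0/1".
    DNA allele balance is encoded back into an integer AD pair over a
    nominal depth of 100 so that read/write round-trips.
    """
    snps = list(snps)
    if not snps:
        raise ValueError("refusing to write an empty VCF")
    subjects = {s.subject_id for s in snps}
    if len(subjects) != 1:
        raise ValueError(f"one subject per VCF, got {sorted(subjects)}")
    subject = snps[0].subject_id
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def chrom_key(s: HetSNP):
        c = s.chrom.removeprefix("chr")
        return (0, int(c)) if c.isdigit() else (1, c)

    ordered = sorted(snps, key=lambda s: (chrom_key(s), s.pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=aseloe{'' if seed is None else f' seed={seed}'}\n")
        seen = []
        for s in ordered:
            if s.chrom not in seen:
                seen.append(s.chrom)
                fh.write(f"##contig=<ID={s.chrom}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
        fh.write('##INFO=<ID=EFFECT,Number=1,Type=String,Description="Variant effect class">\n')
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Population minor allele frequency">\n')
        fh.write('##INFO=<ID=FLAGS,Number=1,Type=String,Description="Positional QC flags">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{subject}\n")
        for s in ordered:
            info = []
            if s.gene_id:
                info.append(f"GENE={s.gene_id}")
            info.append(f"EFFECT={s.effect_class}")
            if s.population_af == s.population_af:
                info.append(f"MAF={s.population_af:.6g}")
            if s.flags:
                info.append("FLAGS=" + ",".join(sorted(s.flags)))
            if s.parental_origin_of_alt == "maternal":
                gt = "1|0"
            elif s.parental_origin_of_alt == "paternal":
                gt = "0|1"
            else:
                gt = "0/1"
            ab = s.dna_allele_balance
            if ab == ab:
                alt_d = int(round(ab * 100))
                ad = f"{100 - alt_d},{alt_d}"
            else:
                ad = ".,."
            gq = int(round(s.genotype_quality)) if s.genotype_quality == s.genotype_quality else "."
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref_base}\t{s.alt_base}\t.\tPASS\t"
                f"{';'.join(info) or '.'}\tGT:GQ:AD\t{gt}:{gq}:{ad}\n"
            )


# ---------------------------------------------------------------------------
# allele counts, gene models, catalogs
# ---------------------------------------------------------------------------

COUNT_COLUMNS = ["subject_id", "tissue", "chrom", "pos", "ref", "alt", "ref_reads", "alt_reads"]


def read_allele_counts(path) -> pd.DataFrame:
    """Read an allele-count TSV into a typed frame; reject malformed rows."""
    df = read_tsv(path)
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df[COUNT_COLUMNS].copy()
    for col in ("ref_reads", "alt_reads"):
        bad = df.index[df[col] < 0]
        if len(bad):
            raise ValueError(f"{path}: negative {col} at row {bad[0]}")
    key = ["subject_id", "tissue", "chrom", "pos"]
    dup = df.duplicated(key)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate allele-count key "
            f"({row.subject_id},{row.tissue},{row.chrom},{row.pos})"
        )
    df["pos"] = df["pos"].astype(int)
    return df


def write_allele_counts(df: pd.DataFrame, path, seed=None, cfg_hash=None) -> None:
    write_tsv(df[COUNT_COLUMNS], path, seed=seed, cfg_hash=cfg_hash)


GENE_COLUMNS = [
    "gene_id", "gene_symbol", "chrom", "strand", "exon_start", "exon_end",
    "isoforms", "coding", "is_hla", "known_imprinted", "polyadenylated",
]


def write_gene_models(genes: Sequence[GeneModel], path, seed=None) -> None:
    rows = []
    for g in genes:
        for start, end, isoforms in g.exons:
            rows.append({
                "gene_id": g.gene_id, "gene_symbol": g.gene_symbol,
                "chrom": g.chrom, "strand": g.strand,
                "exon_start": start, "exon_end": end,
                "isoforms": ",".join(sorted(isoforms)),
                "coding": g.coding_flag, "is_hla": g.is_hla,
                "known_imprinted": g.known_imprinted or "",
                "polyadenylated": g.polyadenylated,
            })
    write_tsv(pd.DataFrame(rows, columns=GENE_COLUMNS), path, seed=seed)


def read_gene_models(path) -> list[GeneModel]:
    df = read_tsv(path, dtype={"known_imprinted": str}, keep_default_na=False)
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    genes = []
    for gid, sub in df.groupby("gene_id", sort=False):
        first = sub.iloc[0]
        exons = tuple(
            (int(r.exon_start), int(r.exon_end), tuple(str(r.isoforms).split(",")))
            for r in sub.itertuples(index=False)
        )
        genes.append(GeneModel(
            gene_id=str(gid), gene_symbol=str(first.gene_symbol),
            chrom=str(first.chrom), strand=str(first.strand), exons=exons,
            coding_flag=_as_bool(first.coding), is_hla=_as_bool(first.is_hla),
            known_imprinted=(str(first.known_imprinted) or None),
            polyadenylated=_as_bool(first.polyadenylated),
        ))
    return genes


def _as_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in {"true", "1", "yes"}
    return bool(x)


def write_imprint_catalog(df: pd.DataFrame, path, seed=None) -> None:
    write_tsv(df[["gene_id", "expressed_parent"]], path, seed=seed)


def read_imprint_catalog(path) -> pd.DataFrame:
    df = read_tsv(path)
    bad = ~df["expressed_parent"].isin(["maternal", "paternal"])
    if bad.any():
        raise ValueError(f"{path}: bad expressed_parent at row {df.index[bad][0]}")
    return df[["gene_id", "expressed_parent"]]


def write_fetal_reference(rpm: pd.Series, path, seed=None) -> None:
    df = rpm.rename("fetal_rpm").rename_axis("gene_id").reset_index()
    write_tsv(df, path, seed=seed)


def read_fetal_reference(path) -> pd.Series:
    df = read_tsv(path)
    if (df["fetal_rpm"] < 0).any():
        raise ValueError(f"{path}: negative fetal r.p.m.")
    return df.set_index("gene_id")["fetal_rpm"]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def compute_rpm(counts: pd.DataFrame, samples: pd.DataFrame) -> ExpressionTable:
    """Normalise gene x sample read counts to reads per million aligned.

    ``samples`` must carry total_aligned_reads per sample; a zero or
    negative total is an error rather than a silent NaN.
    """
    return ExpressionTable(counts=counts.copy(), samples=samples.copy())


def write_expression(expr: ExpressionTable, counts_path, samples_path, seed=None, cfg_hash=None) -> None:
    write_tsv(expr.counts.rename_axis("gene_id"), counts_path, seed=seed, cfg_hash=cfg_hash, index=True)
    write_tsv(expr.samples.rename_axis("sample_id"), samples_path, seed=seed, cfg_hash=cfg_hash, index=True)


def read_expression(counts_path, samples_path) -> ExpressionTable:
    counts = read_tsv(counts_path).set_index("gene_id")
    samples = read_tsv(samples_path).set_index("sample_id")
    return ExpressionTable(counts=counts, samples=samples)
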