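"""Nonsense-mediated decay detection at heterozygous LOF variants.

A het variant whose annotation is loss-of-function (nonsense, frameshift or
canonical splice) is evidence of NMD when the allele carrying it is
under-expressed: the normal/LOF read ratio must exceed 4 and the exact
binomial P value (two-sided, p0 = 0.5), Bonferroni-corrected by the number
of het LOF variants in that subject — not by the number of expressed genes —
must be below 0.01. Direction matters: monoallelic expression *of* the LOF
allele is not NMD however significant.

The LOF allele is the ALT base of the variant, since the effect annotation
describes the alternate allele; variants whose LOF allele cannot be
identified are skipped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from aseloe.ase import binomial_ase_pvalue
from aseloe.io import LOF_EFFECT_CLASSES

__all__ = ["NMDConfig", "NMDCall", "call_nmd", "nmd_fraction"]

log = logging.getLogger("aseloe.nmd")


@dataclass(frozen=True)
class NMDConfig:
    min_bias: float = 4.0        # strict: "fourfold less" is ratio > 4
    corrected_p_max: float = 0.01
    #: which effect classes enter the evaluable set; Table-style analyses
    #: sometimes restrict to nonsense only.
    effect_classes: frozenset = LOF_EFFECT_CLASSES


@dataclass(frozen=True)
class NMDCall:
    gene_id: str
    subject_id: str
    tissue: str
    chrom: str
    pos: int
    lof_allele_reads: int
    normal_allele_reads: int
    nmd_bias: float
    p_value: float
    corrected_p: float
    is_nmd: bool


def call_nmd(lof_records: pd.DataFrame, cfg: NMDConfig = NMDConfig()) -> pd.DataFrame:
    """Call NMD for every het LOF variant with RNA coverage.

    ``lof_records`` rows combine genotype and counts (columns subject_id,
    tissue, gene_id, chrom, pos, ref, alt, effect_class, ref_reads,
    alt_reads). The Bonferroni divisor k is the subject's number of
    distinct LOF variants present in the table. Returns one row per variant
    per sample with bias, P, corrected P and verdict.
    """
    df = lof_records[lof_records["effect_class"].isin(cfg.effect_classes)].copy()
    if df.empty:
        return pd.DataFrame(columns=[
            "gene_id", "subject_id", "tissue", "chrom", "pos",
            "lof_allele_reads", "normal_allele_reads", "nmd_bias",
            "p_value", "corrected_p", "is_nmd",
        ])
    n_unidentified = int((df["alt"].isna() | (df["alt"] == "")).sum())
    if n_unidentified:
        log.warning("skipping %d LOF variants with unidentifiable LOF allele", n_unidentified)
        df = df[~(df["alt"].isna() | (df["alt"] == ""))]
    k_per_subject = (
        df.drop_duplicates(["subject_id", "chrom", "pos"])
        .groupby("subject_id").size()
    )
    rows = []
    for r in df.itertuples(index=False):
        lof, normal = int(r.alt_reads), int(r.ref_reads)
        if lof + normal == 0:
            continue
        bias = normal / lof if lof > 0 else float("inf")
        p, _ = binomial_ase_pvalue(normal, lof, m=1)
        k = int(k_per_subject[r.subject_id])
        cp = min(1.0, k * p)
        is_nmd = (normal > lof) and (bias > cfg.min_bias) and (cp < cfg.corrected_p_max)
        rows.append({
            "gene_id": r.gene_id, "subject_id": r.subject_id, "tissue": r.tissue,
            "chrom": r.chrom, "pos": int(r.pos),
            "lof_allele_reads": lof, "normal_allele_reads": normal,
            "nmd_bias": bias, "p_value": p, "corrected_p": cp, "is_nmd": is_nmd,
        })
    return pd.DataFrame(rows)


def nmd_fraction(calls: pd.DataFrame) -> float:
    """Fraction of evaluable LOF genes that exhibit NMD.

    A gene counts once per subject; it exhibits NMD when any of its LOF
    variants is called in any tissue. The estimate carries the usual
    small-denominator caveat — with few evaluable genes the binomial
    standard error is large.
    """
    if calls.empty:
        raise ValueError("no evaluable LOF genes")
    per_gene = calls.groupby(["gene_id", "subject_id"])["is_nmd"].any()
    return float(per_gene.mean())
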