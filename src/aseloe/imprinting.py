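"""Imprinted-gene assessment and parental-origin bias tests.

Known imprinted genes (from a catalog of gene -> expressed parent) are
scored for ASE across both cohorts: a subject is informative for a gene
when it carries a QC-passing het SNP there, and shows ASE when the gene has
an extreme-ASE event in any of the subject's tissues. A gene is classed as
imprinted in heart when at least half of informative subjects (combined
cohorts, by default) show ASE. The expressed parental allele is the
majority vote of trio-phased subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import math

import pandas as pd
from scipy import stats

__all__ = [
    "ImprintingSummary", "pct_ase", "summarize_imprinted_gene",
    "summarize_imprinted_genes", "fisher_exact_2x2", "parental_bias_tests",
]


@dataclass(frozen=True)
class ImprintingSummary:
    gene_id: str
    case_ase_num: int
    case_ase_den: int
    control_ase_num: int
    control_ase_den: int
    pct_ase: int
    expressed_parent: str  # "maternal" / "paternal" / "indeterminate"
    classed_imprinted_in_heart: bool


def pct_ase(case_num: int, case_den: int, control_num: int, control_den: int) -> int:
    """Integer percent of subjects with the silenced allele, combined cohorts."""
    den = case_den + control_den
    if den == 0:
        raise ValueError("no informative subjects")
    return round(100 * (case_num + control_num) / den)


def summarize_imprinted_gene(
    gene_id: str,
    subject_ase: Mapping[str, bool],
    cohort_of: Mapping[str, str],
    subject_parent_votes: Mapping[str, str] | None = None,
    combined_rule: bool = True,
) -> ImprintingSummary | None:
    """Score one catalog gene from per-subject ASE verdicts.

    ``subject_ase`` maps each informative subject to whether it shows ASE;
    ``subject_parent_votes`` maps phased ASE subjects to the parent of
    their expressed allele. Returns None when no subject is informative.
    With ``combined_rule`` the >= 50% membership test uses the combined
    cohorts; otherwise each cohort must reach 50% on its own.
    """
    if not subject_ase:
        return None
    nums = {"case": 0, "control": 0}
    dens = {"case": 0, "control": 0}
    for subject, has_ase in subject_ase.items():
        grp = cohort_of.get(subject, "case")
        dens[grp] += 1
        nums[grp] += bool(has_ase)
    pct = pct_ase(nums["case"], dens["case"], nums["control"], dens["control"])
    if combined_rule:
        classed = (nums["case"] + nums["control"]) / (dens["case"] + dens["control"]) >= 0.5
    else:
        classed = all(
            (nums[g] / dens[g] >= 0.5) for g in ("case", "control") if dens[g] > 0
        )
    parent = "indeterminate"
    votes = [v for v in (subject_parent_votes or {}).values() if v in ("maternal", "paternal")]
    if votes:
        n_mat = votes.count("maternal")
        n_pat = votes.count("paternal")
        if n_mat and n_pat:
            parent = "indeterminate"  # conflicting phased subjects
        else:
            parent = "maternal" if n_mat else "paternal"
    return ImprintingSummary(
        gene_id=gene_id,
        case_ase_num=nums["case"], case_ase_den=dens["case"],
        control_ase_num=nums["control"], control_ase_den=dens["control"],
        pct_ase=pct, expressed_parent=parent,
        classed_imprinted_in_heart=classed,
    )


def summarize_imprinted_genes(
    ase_calls: pd.DataFrame,
    catalog: pd.DataFrame,
    cohort_of: Mapping[str, str],
    fetal_reference: pd.Series | None = None,
    fetal_rpm_min: float = 2.0,
    combined_rule: bool = True,
) -> pd.DataFrame:
    """Score every catalog gene from the per-sample ASE summary table.

    ``ase_calls`` is the output of :func:`aseloe.ase.call_extreme_ase` and
    must include the imprinted genes (they are excluded from the
    *non-imprinted* call set but still tested). Catalog genes below the
    fetal-heart expression cut are excluded up front.
    """
    genes = catalog["gene_id"].tolist()
    if fetal_reference is not None:
        genes = [g for g in genes if float(fetal_reference.get(g, 0.0)) >= fetal_rpm_min]
    rows = []
    for gene in genes:
        sub = ase_calls[ase_calls["gene_id"] == gene]
        if sub.empty:
            continue
        subject_ase = sub.groupby("subject_id")["is_extreme_ase"].any().to_dict()
        votes = {}
        for r in sub[sub["is_extreme_ase"]].itertuples(index=False):
            if r.mat_sum > r.pat_sum:
                votes[r.subject_id] = "maternal"
            elif r.pat_sum > r.mat_sum:
                votes[r.subject_id] = "paternal"
        summary = summarize_imprinted_gene(gene, subject_ase, cohort_of, votes, combined_rule)
        if summary is not None:
            rows.append(summary.__dict__)
    return pd.DataFrame(rows, columns=[
        "gene_id", "case_ase_num", "case_ase_den", "control_ase_num",
        "control_ase_den", "pct_ase", "expressed_parent", "classed_imprinted_in_heart",
    ])


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple:
    """Two-sided conditional Fisher exact test on [[a, b], [c, d]].

    Returns (p, odds_ratio) with the sample odds ratio a*d / (b*c)
    (infinite on a zero denominator with a nonzero numerator). The P value
    sums the hypergeometric probabilities, over tables with the observed
    margins, that do not exceed the observed table's.
    """
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0 or v != int(v):
            raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
    if a + b + c + d == 0:
        raise ValueError("all-zero contingency table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c > 0:
        oddsratio = (a * d) / (b * c)
    else:
        oddsratio = math.inf if a * d > 0 else math.nan
    return float(p), float(oddsratio)


def parental_bias_tests(
    gene_table: pd.DataFrame,
    cluster_of: Mapping[str, str] | None = None,
) -> dict:
    """Test whether in-heart ASE is skewed toward paternally expressed genes.

    ``gene_table`` needs columns gene_id, expressed_parent (catalog label)
    and ase_in_heart (boolean). Two 2x2 Fisher tests are run: (i) all
    catalog genes, maternal vs paternal x ASE/biallelic; (ii) the same
    restricted to genes inside imprinted clusters, when ``cluster_of``
    gives the cluster-member gene ids. Each entry reports the table and
    its P value.
    """
    def table_for(sub: pd.DataFrame):
        mat = sub[sub["expressed_parent"] == "maternal"]
        pat = sub[sub["expressed_parent"] == "paternal"]
        return [
            [int(mat["ase_in_heart"].sum()), int((~mat["ase_in_heart"]).sum())],
            [int(pat["ase_in_heart"].sum()), int((~pat["ase_in_heart"]).sum())],
        ]

    report: dict = {}
    t1 = table_for(gene_table)
    p1, or1 = fisher_exact_2x2(*t1[0], *t1[1])
    report["maternal_vs_paternal"] = {"table": t1, "p": p1, "odds_ratio": or1}
    if cluster_of is not None:
        clustered = gene_table[gene_table["gene_id"].isin(set(cluster_of))]
        t2 = table_for(clustered)
        p2, or2 = fisher_exact_2x2(*t2[0], *t2[1])
        report["within_clusters"] = {"table": t2, "p": p2, "odds_ratio": or2}
    return report
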