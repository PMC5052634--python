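"""Leave-one-out expression comparison, sample QC, LOE calling and burdens.

Each sample is compared with the mean r.p.m. of all other samples of the
same tissue type: fold = sample / leave-one-out mean, z = (sample - mean) /
sd (sample sd, n-1 denominator), P = two-sided normal tail of z. Tissue
groups need more than four samples. The derived thresholds are computed
from first principles rather than hard-coded:

* downregulated-ASE fold cut: 0.5 allele loss relaxed by 30% -> 0.5 + 0.5*0.3 = 0.65
* upregulated-ASE fold cut: 7.2-fold allele gain relaxed by 30% -> ~5
* LOE significance: two-sided normal tail at z = -3 -> 2.6998e-3

Biallelic LOE requires candidacy — the gene is highly expressed (upper
quartile of expressed genes in the tissue group) with tightly regulated
expression (coefficient of variation <= 0.5, a modelling choice) — plus
fold < 0.1 at the z < -3 significance, restricted to polyadenylated
transcripts. r.p.k.m. (length-normalised) can be derived from gene models
but plays no role in any call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from aseloe.imprinting import fisher_exact_2x2
from aseloe.io import EXPRESSED_RPM_MIN, ExpressionTable

__all__ = [
    "ase_down_fold_threshold", "ase_up_fold_threshold", "loe_p_threshold",
    "ExpressionCallConfig", "ExpressionComparison",
    "loo_compare_all", "loo_compare", "sample_expression_qc",
    "integrate_ase_expression", "call_loe", "burden_fisher",
]


def ase_down_fold_threshold() -> float:
    """Allele loss halves expression; relax by 30%: 0.5 + 0.5 * 0.3."""
    return 0.5 + 0.5 * 0.3


def ase_up_fold_threshold() -> float:
    """Allele gain at the 7.2 operating ratio, relaxed by 30%: 7.2 - 7.2 * 0.3."""
    return 7.2 - 7.2 * 0.3


def loe_p_threshold() -> float:
    """Two-sided normal tail mass at z = -3."""
    return float(2.0 * stats.norm.sf(3.0))


@dataclass(frozen=True)
class ExpressionCallConfig:
    """Thresholds for expression-based classification."""

    ase_down_fold: float = field(default_factory=ase_down_fold_threshold)
    ase_up_fold: float = 5.0  # the operational cut (7.2 relaxed by 30%, ~5)
    ase_p: float = 0.05
    loe_fold: float = 0.1
    loe_p: float = field(default_factory=loe_p_threshold)
    sample_qc_max_diffs: int = 100
    sample_qc_down_fold: float = 0.2
    sample_qc_up_fold: float = 5.0
    sample_qc_p: float = 0.05
    loe_upper_quartile: bool = True
    loe_cv_max: float = 0.5
    min_peers: int = 4  # leave-one-out peers required for any call

    def __post_init__(self):
        for name in ("ase_down_fold", "ase_up_fold", "ase_p", "loe_fold", "loe_p",
                     "sample_qc_down_fold", "sample_qc_up_fold", "sample_qc_p",
                     "loe_cv_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ExpressionComparison:
    gene_id: str
    sample_id: str
    tissue: str
    proband_rpm: float
    loo_mean: float
    loo_sd: float
    n_others: int
    fold: float
    z: float
    p: float


def loo_compare_all(expr: ExpressionTable, min_peers: int = 4) -> pd.DataFrame:
    """Leave-one-out statistics for every gene in every sample, vectorised.

    Tissue groups with fewer than ``min_peers`` other samples are skipped.
    fold is NaN where the peers' mean is zero, z/p are NaN where their sd
    is zero; such cells are excluded from any call downstream.
    """
    frames = []
    for tissue, meta in expr.samples.groupby("tissue"):
        cols = meta.index.tolist()
        n = len(cols)
        if n - 1 < min_peers:
            continue
        X = expr.rpm[cols].to_numpy(dtype=float)
        S = X.sum(axis=1, keepdims=True)
        SS = (X**2).sum(axis=1, keepdims=True)
        m = n - 1
        loo_mean = (S - X) / m
        with np.errstate(invalid="ignore"):
            loo_var = (SS - X**2 - m * loo_mean**2) / (m - 1)
        loo_sd = np.sqrt(np.clip(loo_var, 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = np.where(loo_mean > 0, X / loo_mean, np.nan)
            z = np.where(loo_sd > 0, (X - loo_mean) / loo_sd, np.nan)
        p = 2.0 * stats.norm.sf(np.abs(z))
        long = pd.DataFrame({
            "gene_id": np.repeat(expr.rpm.index.to_numpy(), n),
            "sample_id": np.tile(cols, len(expr.rpm)),
            "tissue": tissue,
            "proband_rpm": X.ravel(),
            "loo_mean": loo_mean.ravel(),
            "loo_sd": loo_sd.ravel(),
            "n_others": m,
            "fold": fold.ravel(),
            "z": z.ravel(),
            "p": p.ravel(),
        })
        frames.append(long)
    if not frames:
        return pd.DataFrame(columns=[
            "gene_id", "sample_id", "tissue", "proband_rpm", "loo_mean",
            "loo_sd", "n_others", "fold", "z", "p"])
    return pd.concat(frames, ignore_index=True)


def loo_compare(expr: ExpressionTable, gene_id: str, sample_id: str,
                min_peers: int = 4) -> ExpressionComparison:
    """Leave-one-out comparison of one gene in one sample."""
    tissue = expr.samples.loc[sample_id, "tissue"]
    peers = expr.samples.index[(expr.samples["tissue"] == tissue)
                               & (expr.samples.index != sample_id)]
    if len(peers) < min_peers:
        raise ValueError(
            f"tissue group {tissue!r} has only {len(peers)} other samples (need > {min_peers})")
    x = float(expr.rpm.loc[gene_id, sample_id])
    others = expr.rpm.loc[gene_id, peers].to_numpy(dtype=float)
    mean, sd = float(others.mean()), float(others.std(ddof=1))
    fold = x / mean if mean > 0 else float("nan")
    z = (x - mean) / sd if sd > 0 else float("nan")
    p = float(2 * stats.norm.sf(abs(z))) if z == z else float("nan")
    return ExpressionComparison(
        gene_id=gene_id, sample_id=sample_id, tissue=tissue, proband_rpm=x,
        loo_mean=mean, loo_sd=sd, n_others=len(peers), fold=fold, z=z, p=p)


def sample_expression_qc(
    comparisons: pd.DataFrame,
    cfg: ExpressionCallConfig = ExpressionCallConfig(),
) -> pd.DataFrame:
    """Exclude samples with >100 highly significant expression differences.

    A difference counts when fold < 0.2 with P < 0.05 or fold > 5 with
    P < 0.05; such samples are degraded or mislabelled, not biology.
    """
    sig = (
        (comparisons["p"] < cfg.sample_qc_p)
        & ((comparisons["fold"] < cfg.sample_qc_down_fold)
           | (comparisons["fold"] > cfg.sample_qc_up_fold))
    )
    counts = sig.groupby(comparisons["sample_id"]).sum()
    counts = counts.reindex(comparisons["sample_id"].unique(), fill_value=0)
    out = counts.rename("n_differences").rename_axis("sample_id").reset_index()
    out["verdict"] = np.where(out["n_differences"] > cfg.sample_qc_max_diffs, "exclude", "keep")
    return out


def integrate_ase_expression(
    ase_calls: pd.DataFrame,
    comparisons: pd.DataFrame,
    samples: pd.DataFrame,
    cfg: ExpressionCallConfig = ExpressionCallConfig(),
) -> pd.DataFrame:
    """Label each extreme-ASE event up/down/unchanged by expression.

    Downregulated: fold < 0.65 with P < 0.05; upregulated: fold > 5 with
    P < 0.05; otherwise unchanged. Events without a usable comparison
    (tissue group too small, undefined fold) stay unlabelled.
    """
    events = ase_calls[ase_calls["called"]].copy()
    sample_of = {
        (r.subject_id, r.tissue): idx
        for idx, r in samples.iterrows()
    }
    events["sample_id"] = [
        sample_of.get((r.subject_id, r.tissue)) for r in events.itertuples(index=False)
    ]
    merged = events.merge(
        comparisons[["gene_id", "sample_id", "fold", "z", "p"]],
        on=["gene_id", "sample_id"], how="left",
    )
    label = np.full(len(merged), "unchanged", dtype=object)
    usable = merged["fold"].notna() & merged["p"].notna()
    down = usable & (merged["fold"] < cfg.ase_down_fold) & (merged["p"] < cfg.ase_p)
    up = usable & (merged["fold"] > cfg.ase_up_fold) & (merged["p"] < cfg.ase_p)
    label[~usable] = "unevaluated"
    label[down.to_numpy()] = "downregulated"
    label[up.to_numpy()] = "upregulated"
    merged["expression_class"] = label
    return merged


def call_loe(
    comparisons: pd.DataFrame,
    expr: ExpressionTable,
    cfg: ExpressionCallConfig = ExpressionCallConfig(),
    polyadenylated: Mapping[str, bool] | None = None,
    excluded_samples: Iterable[str] = (),
) -> pd.DataFrame:
    """Call biallelic loss of expression.

    Candidacy per tissue group: the cell's leave-one-out mean r.p.m.
    reaches the upper quartile of the tissue's expressed genes (group mean
    >= 2 r.p.m.) and the leave-one-out coefficient of variation is at most
    ``loe_cv_max``. A
    candidate cell is LOE when fold < 0.1 and P < 2.7e-3 (z < -3), limited
    to polyadenylated transcripts.
    """
    comp = comparisons[~comparisons["sample_id"].isin(set(excluded_samples))].copy()
    group_mean = (
        comp.groupby(["tissue", "gene_id"])["proband_rpm"].mean().rename("tissue_mean")
    )
    comp = comp.join(group_mean, on=["tissue", "gene_id"])
    if cfg.loe_upper_quartile:
        q3 = (
            group_mean[group_mean >= EXPRESSED_RPM_MIN]
            .groupby(level="tissue").quantile(0.75).rename("tissue_q3")
        )
        comp = comp.join(q3, on="tissue")
        # the focal sample's own knockdown must not disqualify its gene,
        # so candidacy is judged on the leave-one-out mean
        candidate = comp["loo_mean"] >= comp["tissue_q3"]
    else:
        candidate = comp["loo_mean"] >= EXPRESSED_RPM_MIN
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = comp["loo_sd"] / comp["loo_mean"]
    candidate &= cv <= cfg.loe_cv_max
    if polyadenylated is not None:
        poly = comp["gene_id"].map(polyadenylated)
        candidate &= poly.isna() | (poly == True)  # noqa: E712
    comp["is_candidate"] = candidate.fillna(False)
    comp["is_loe"] = (
        comp["is_candidate"]
        & (comp["fold"] < cfg.loe_fold)
        & (comp["p"] < cfg.loe_p)
    ).fillna(False)
    return comp


def burden_fisher(case_hits: int, case_n: int, control_hits: int, control_n: int) -> tuple:
    """Fisher exact burden comparison of hit rates between cohorts."""
    if case_hits > case_n or control_hits > control_n:
        raise ValueError("hits exceed totals")
    return fisher_exact_2x2(case_hits, case_n - case_hits,
                            control_hits, control_n - control_hits)
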