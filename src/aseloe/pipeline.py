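"""End-to-end orchestration: qc -> ase -> imprint -> nmd -> expr -> integrate.

Execution is two-pass where cohort-level filters demand it: SNP bias flags
and ASE tallies are collected across all subjects before per-subject calls
are finalised (the common-biased-SNP and common-ASE-gene filters), and the
pass-1 statistics are materialised to disk for auditability. Every output
TSV header records the package version, config hash and seed, and all stage
outputs are pure functions of (inputs, config, seed) — rerunning a config
byte-identically reproduces the bundle.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from aseloe import io as aio
from aseloe.ase import ASEConfig, assign_snp_reads, call_extreme_ase, summarize_genes
from aseloe.expression import (
    ExpressionCallConfig, burden_fisher, call_loe, integrate_ase_expression,
    loo_compare_all, sample_expression_qc,
)
from aseloe.imprinting import summarize_imprinted_genes
from aseloe.nmd import NMDConfig, call_nmd, nmd_fraction
from aseloe.qc import QCConfig, run_qc
from aseloe.simulate import SyntheticCohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("aseloe.pipeline")


@dataclass
class PipelineConfig:
    qc: QCConfig = field(default_factory=QCConfig)
    ase: ASEConfig = field(default_factory=ASEConfig)
    nmd: NMDConfig = field(default_factory=NMDConfig)
    expr: ExpressionCallConfig = field(default_factory=ExpressionCallConfig)
    seed: int = 0

    def hash(self) -> str:
        return aio.config_hash({
            "qc": dataclasses.asdict(self.qc),
            "ase": dataclasses.asdict(self.ase),
            "nmd": {**dataclasses.asdict(self.nmd),
                    "effect_classes": sorted(self.nmd.effect_classes)},
            "expr": dataclasses.asdict(self.expr),
            "seed": self.seed,
        })


@dataclass
class PipelineResult:
    qc_attrition: pd.DataFrame
    subject_qc: pd.DataFrame
    ase_calls: pd.DataFrame
    imprinting: pd.DataFrame
    nmd_calls: pd.DataFrame
    comparisons: pd.DataFrame
    sample_qc: pd.DataFrame
    loe_calls: pd.DataFrame
    integrated: pd.DataFrame
    summary: dict


def _stage(name: str):
    log.info("pipeline stage: %s", name)


def run_pipeline(
    cohort: SyntheticCohort,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on an in-memory cohort; optionally write the bundle.

    Any stage failure propagates with the stage name prepended so the
    offending record is identifiable from the traceback.
    """
    cfg = config or PipelineConfig()
    chash, seed = cfg.hash(), cfg.seed
    n_subjects_total = len(cohort.cohort_of)

    stage = "qc"
    try:
        _stage(stage)
        qc_res = run_qc(
            cohort.snps, cohort.allele_counts, cohort.gene_models,
            cohort.fetal_reference, cohort.cohort_of,
            indels=cohort.indels if len(cohort.indels) else None, cfg=cfg.qc,
        )

        stage = "ase"
        _stage(stage)
        assigned = assign_snp_reads(qc_res.passed)
        summaries = summarize_genes(assigned, qc_res.m_per_sample)
        imprinted_genes = set(cohort.imprint_catalog["gene_id"])
        ase_calls = call_extreme_ase(
            summaries, known_imprinted=imprinted_genes, cfg=cfg.ase,
            cohort_of=cohort.cohort_of, n_subjects_total=n_subjects_total,
            qc_cfg=cfg.qc,
        )

        stage = "imprint"
        _stage(stage)
        imprinting = summarize_imprinted_genes(
            ase_calls, cohort.imprint_catalog, cohort.cohort_of,
            fetal_reference=cohort.fetal_reference, fetal_rpm_min=cfg.qc.fetal_rpm_min,
        )

        stage = "nmd"
        _stage(stage)
        # NMD variants are exempt from the common-bias filter, so the
        # evaluable set comes from the pre-cascade records with coverage.
        lof = qc_res.records[
            qc_res.records["effect_class"].isin(cfg.nmd.effect_classes)
            & ~qc_res.records["failed_filters"].str.contains("min_coverage|subject_excluded")
        ]
        nmd_calls = call_nmd(lof, cfg=cfg.nmd)

        stage = "expr"
        _stage(stage)
        comparisons = loo_compare_all(cohort.expression, min_peers=cfg.expr.min_peers)
        sample_qc = sample_expression_qc(comparisons, cfg=cfg.expr)
        bad_samples = set(sample_qc.loc[sample_qc["verdict"] == "exclude", "sample_id"])
        polyA = {g.gene_id: g.polyadenylated for g in cohort.gene_models}
        loe_calls = call_loe(comparisons, cohort.expression, cfg=cfg.expr,
                             polyadenylated=polyA, excluded_samples=bad_samples)

        stage = "integrate"
        _stage(stage)
        integrated = integrate_ase_expression(
            ase_calls, comparisons, cohort.expression.samples, cfg=cfg.expr)

        # burden tests: subjects with expression-changed ASE / with LOE
        subj = cohort.expression.samples["subject_id"]
        cohort_counts = pd.Series(cohort.cohort_of).value_counts()
        changed = integrated[integrated["expression_class"].isin(["upregulated", "downregulated"])]
        changed_subjects = set(changed["subject_id"])
        loe_rows = loe_calls[loe_calls["is_loe"]].merge(
            cohort.expression.samples[["subject_id"]], left_on="sample_id", right_index=True)
        loe_subjects = set(loe_rows["subject_id"])
        case_n = int(cohort_counts.get("case", 0))
        ctrl_n = int(cohort_counts.get("control", 0))

        def split(subjects: set) -> tuple:
            case = sum(cohort.cohort_of.get(s) == "case" for s in subjects)
            ctrl = sum(cohort.cohort_of.get(s) == "control" for s in subjects)
            return case, ctrl

        summary = {
            "n_snp_records": int(len(qc_res.records)),
            "n_snp_records_passed": int(len(qc_res.passed)),
            "n_subjects_excluded": int((qc_res.subject_qc["verdict"] == "exclude").sum()),
            "n_extreme_ase_events": int(ase_calls["called"].sum()),
            "n_imprinted_gene_ase_events": int(
                (ase_calls["is_extreme_ase"] & ase_calls["is_imprinted_gene"]).sum()),
            "n_genes_imprinted_in_heart": int(imprinting["classed_imprinted_in_heart"].sum())
                if len(imprinting) else 0,
            "n_nmd_calls": int(nmd_calls["is_nmd"].sum()) if len(nmd_calls) else 0,
            "nmd_fraction": nmd_fraction(nmd_calls) if len(nmd_calls) else float("nan"),
            "n_samples_excluded_expression": int(len(bad_samples)),
            "n_loe_events": int(loe_calls["is_loe"].sum()),
            "n_ase_expression_changed": int(len(changed)),
        }
        if case_n and ctrl_n:
            ch_case, ch_ctrl = split(changed_subjects)
            loe_case, loe_ctrl = split(loe_subjects)
            summary["burden_ase_expression_p"] = burden_fisher(
                ch_case, case_n, ch_ctrl, ctrl_n)[0]
            summary["burden_loe_p"] = burden_fisher(loe_case, case_n, loe_ctrl, ctrl_n)[0]
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    result = PipelineResult(
        qc_attrition=qc_res.attrition, subject_qc=qc_res.subject_qc,
        ase_calls=ase_calls, imprinting=imprinting, nmd_calls=nmd_calls,
        comparisons=comparisons, sample_qc=sample_qc, loe_calls=loe_calls,
        integrated=integrated, summary=summary,
    )
    if out_dir is not None:
        _write_bundle(result, qc_res, Path(out_dir), seed, chash)
    return result


def _write_bundle(result: PipelineResult, qc_res, out: Path, seed, chash) -> None:
    out.mkdir(parents=True, exist_ok=True)
    kw = {"seed": seed, "cfg_hash": chash}
    # pass-1 cohort statistics, materialised for audit
    aio.write_tsv(qc_res.records[
        ["subject_id", "tissue", "chrom", "pos", "gene_id", "ref_reads",
         "alt_reads", "failed_filters"]], out / "qc_records.tsv", **kw)
    aio.write_tsv(result.qc_attrition, out / "qc_attrition.tsv", **kw)
    aio.write_tsv(result.subject_qc, out / "subject_qc.tsv", **kw)
    aio.write_tsv(result.ase_calls, out / "ase_calls.tsv", **kw)
    aio.write_tsv(result.imprinting, out / "imprinting.tsv", **kw)
    aio.write_tsv(result.nmd_calls, out / "nmd_calls.tsv", **kw)
    aio.write_tsv(result.comparisons, out / "expression_comparisons.tsv", **kw)
    aio.write_tsv(result.sample_qc, out / "sample_qc.tsv", **kw)
    aio.write_tsv(result.loe_calls[result.loe_calls["is_loe"]], out / "loe_calls.tsv", **kw)
    aio.write_tsv(result.integrated, out / "ase_expression_integrated.tsv", **kw)
    summary = pd.DataFrame(sorted(result.summary.items()), columns=["metric", "value"])
    aio.write_tsv(summary, out / "summary.tsv", **kw)
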