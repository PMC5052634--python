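"""Shared fixtures: synthetic cohorts generated once per session."""

from __future__ import annotations

import math
from fractions import Fraction

import pandas as pd
import pytest

from aseloe.pipeline import PipelineConfig, run_pipeline
from aseloe.qc import QCConfig, run_qc
from aseloe.simulate import (
    f1_validation_config, generate_cohort, inject_mapping_bias, study_config,
)

STUDY_SEED = 7


# ---------------------------------------------------------------------------
# independent oracles (pure integer / rational arithmetic)
# ---------------------------------------------------------------------------

def binomial_two_sided_oracle(H: int, L: int) -> float:
    """Exact doubled upper tail of Binomial(H+L, 1/2), by enumeration."""
    n = H + L
    hi = max(H, L)
    tail = sum(math.comb(n, k) for k in range(hi, n + 1))
    return min(1.0, float(2 * Fraction(tail, 2**n)))


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact conditional two-sided Fisher P by hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def pmf(x: int) -> Fraction:
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)

    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = sum((q := pmf(x)) for x in range(lo, hi + 1) if pmf(x) <= p_obs)
    return float(total)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def study_cohort():
    """Study-scale cohort with every event class plus mapping-bias contamination."""
    clean = generate_cohort(study_config(seed=STUDY_SEED))
    contaminated = inject_mapping_bias(clean, 0.04)
    return clean, contaminated


@pytest.fixture(scope="session")
def study_result(study_cohort):
    _, contaminated = study_cohort
    return run_pipeline(contaminated, PipelineConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def study_qc(study_cohort):
    _, contaminated = study_cohort
    return run_qc(
        contaminated.snps, contaminated.allele_counts, contaminated.gene_models,
        contaminated.fetal_reference, contaminated.cohort_of,
        indels=contaminated.indels, cfg=QCConfig(),
    )


@pytest.fixture(scope="session")
def f1_cohorts():
    """Fully phased validation cohorts over several seeds, with QC applied."""
    out = []
    for seed in range(10, 16):
        cohort = generate_cohort(f1_validation_config(seed=seed))
        qc_res = run_qc(cohort.snps, cohort.allele_counts, cohort.gene_models,
                        cohort.fetal_reference, cohort.cohort_of, cfg=QCConfig())
        out.append((cohort, qc_res))
    return out


def ase_recovery(cohort, ase_calls: pd.DataFrame) -> tuple:
    """(recovered, total) injected ASE events called in any tissue."""
    truth = cohort.truth["ase"]
    called = ase_calls[ase_calls["is_extreme_ase"]]
    pairs = set(zip(called["gene_id"], called["subject_id"]))
    hits = sum((r.gene_id, r.subject_id) in pairs for r in truth.itertuples())
    return hits, len(truth)


def loe_recovery(cohort, loe_calls: pd.DataFrame) -> tuple:
    """(recovered, total) injected LOE events called in any sample."""
    truth = cohort.truth["loe"]
    hits_df = loe_calls[loe_calls["is_loe"]].merge(
        cohort.expression.samples[["subject_id"]],
        left_on="sample_id", right_index=True)
    pairs = set(zip(hits_df["gene_id"], hits_df["subject_id"]))
    hits = sum((r.gene_id, r.subject_id) in pairs for r in truth.itertuples())
    return hits, len(truth)
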