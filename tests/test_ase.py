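"""Compound allele bias, binomial ASE test, calling and phasing validation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aseloe.ase import (
    ASEConfig, assign_snp_reads, binomial_ase_pvalue, call_extreme_ase,
    compound_allele_bias, evaluate_phasing_grid, phased_unphased_concordance,
    summarize_genes,
)
from aseloe.qc import QCConfig, run_qc
from aseloe.simulate import (
    SimulationConfig, AseEvent, generate_cohort, null_config, strong_events_config,
)
from tests.conftest import binomial_two_sided_oracle


def counts_frame(rows):
    """rows: (pos, origin, ref_reads, alt_reads[, gene, subject])"""
    out = []
    for r in rows:
        pos, origin, ref, alt = r[:4]
        out.append({
            "subject_id": r[5] if len(r) > 5 else "s1", "tissue": "t1",
            "chrom": "chr1", "pos": pos, "ref": "A", "alt": "G",
            "gene_id": r[4] if len(r) > 4 else "G1",
            "parental_origin": origin, "effect_class": "missense",
            "ref_reads": ref, "alt_reads": alt,
        })
    return pd.DataFrame(out)


class TestAssign:
    def test_maternal_alt_reads_bin_to_maternal(self):
        out = assign_snp_reads(counts_frame([(100, "maternal", 10, 30)]))
        assert out.loc[0, ["mat", "pat", "higher", "lower"]].tolist() == [30, 10, 0, 0]

    def test_unphased_higher_lower(self):
        out = assign_snp_reads(counts_frame([(100, "unknown", 30, 10)]))
        assert out.loc[0, ["mat", "pat", "higher", "lower"]].tolist() == [0, 0, 30, 10]

    def test_tie_contributes_no_direction_but_counts(self):
        df = counts_frame([(100, "unknown", 10, 10), (200, "unknown", 30, 5)])
        summaries = summarize_genes(assign_snp_reads(df), {})
        row = summaries.iloc[0]
        assert row["higher_sum"] == 30 and row["lower_sum"] == 5
        assert row["n_snps_used"] == 2

    def test_use_phase_false_ignores_origin(self):
        out = assign_snp_reads(counts_frame([(100, "maternal", 10, 30)]), use_phase=False)
        assert out.loc[0, ["mat", "pat", "higher", "lower"]].tolist() == [0, 0, 30, 10]


class TestCompoundBias:
    def test_maternal_dominant_formula(self):
        bias, H, L = compound_allele_bias(36, 5, 10, 2)
        assert bias == pytest.approx(46 / 7)
        assert (H, L) == (46, 7)

    def test_paternal_dominant_mirrors(self):
        bias, _, _ = compound_allele_bias(5, 36, 10, 2)
        assert bias == pytest.approx(46 / 7)

    def test_unknown_inheritance_boundary(self):
        bias, _, _ = compound_allele_bias(0, 0, 36, 5)
        assert bias == pytest.approx(7.2)

    def test_zero_denominator_is_infinite(self):
        bias, H, L = compound_allele_bias(50, 0, 0, 0)
        assert math.isinf(bias) and (H, L) == (50, 0)

    def test_nonzero_parental_tie_falls_back_to_unphased_form(self):
        bias, H, L = compound_allele_bias(10, 10, 30, 5)
        assert (H, L) == (30, 5)
        assert bias == pytest.approx(6.0)


class TestBinomialP:
    def test_frozen_oracle_values(self):
        # enumeration oracle: 2*sum_{k>=36} C(41,k)/2^41
        p, cp = binomial_ase_pvalue(36, 5, m=1)
        assert p == pytest.approx(7.8415723692e-07, rel=1e-9)
        assert p == pytest.approx(binomial_two_sided_oracle(36, 5), rel=1e-12)

    def test_symmetric_center_caps_at_one(self):
        p, _ = binomial_ase_pvalue(5, 5)
        assert p == 1.0

    def test_single_term_tail_and_bonferroni(self):
        p, cp = binomial_ase_pvalue(10, 0, m=100)
        assert p == pytest.approx(2 * 2**-10)
        assert cp == pytest.approx(100 * 2 * 2**-10)

    def test_zero_reads_undefined(self):
        with pytest.raises(ValueError):
            binomial_ase_pvalue(0, 0)

    @given(st.integers(0, 200), st.integers(0, 200))
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, H, L):
        if H + L == 0:
            return
        p, _ = binomial_ase_pvalue(H, L)
        assert p == pytest.approx(binomial_two_sided_oracle(H, L), abs=1e-12)

    def test_monotone_in_h_at_fixed_n(self):
        n = 60
        ps = [binomial_ase_pvalue(H, n - H)[0] for H in range(n // 2, n + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))
        biases = [compound_allele_bias(0, 0, H, n - H)[0] for H in range(n // 2 + 1, n + 1)]
        assert all(a <= b for a, b in zip(biases, biases[1:]))


def test_statistic_is_allele_symmetric():
    """Relabeling which base is REF leaves bias and P unchanged."""
    rows = [(100, "maternal", 10, 30), (200, "unknown", 25, 4), (300, "unknown", 8, 8)]
    flipped = [(p, {"maternal": "paternal", "paternal": "maternal"}.get(o, o), a, r)
               for (p, o, r, a) in rows]
    s1 = summarize_genes(assign_snp_reads(counts_frame(rows)), {})
    s2 = summarize_genes(assign_snp_reads(counts_frame(flipped)), {})
    for col in ("allele_bias", "binomial_p", "H", "L"):
        assert s1.loc[0, col] == s2.loc[0, col]


class TestCallBoundaries:
    def _summary(self, bias, cp, H=40):
        return pd.DataFrame([{
            "gene_id": "G1", "subject_id": "s1", "tissue": "t1",
            "mat_sum": 0, "pat_sum": 0, "higher_sum": H, "lower_sum": 5,
            "H": H, "L": 5, "allele_bias": bias, "n_snps_used": 2,
            "binomial_p": cp, "corrected_p": cp,
        }])

    @pytest.mark.parametrize("bias,cp,called", [
        (7.2, 0.009, True),
        (7.1, 1e-6, False),
        (20.0, 0.02, False),
        (float("inf"), 0.001, True),
    ])
    def test_joint_rule(self, bias, cp, called):
        out = call_extreme_ase(self._summary(bias, cp))
        assert bool(out["is_extreme_ase"].iloc[0]) is called

    def test_low_read_infinite_bias_not_called(self):
        out = call_extreme_ase(self._summary(float("inf"), 0.001, H=4))
        assert not out["is_extreme_ase"].iloc[0]

    def test_imprinted_genes_excluded_from_call_set(self):
        out = call_extreme_ase(self._summary(9.0, 0.001), known_imprinted={"G1"})
        assert out["is_extreme_ase"].iloc[0] and not out["called"].iloc[0]


@pytest.fixture(scope="module")
def strong_cohort_qc():
    cohort = generate_cohort(strong_events_config(seed=21))
    qc_res = run_qc(cohort.snps, cohort.allele_counts, cohort.gene_models,
                    cohort.fetal_reference, cohort.cohort_of, cfg=QCConfig())
    return cohort, qc_res


class TestPhasingValidation:
    def test_strong_events_called_identically_with_and_without_phase(self, strong_cohort_qc):
        cohort, qc_res = strong_cohort_qc
        report = phased_unphased_concordance(qc_res.passed, qc_res.m_per_sample)
        assert report["phased"]
        assert report["symmetric_difference"] == set()

    def test_no_events_means_no_calls_either_way(self):
        cohort = generate_cohort(null_config(seed=30, n_subjects=4, n_controls=2))
        qc_res = run_qc(cohort.snps, cohort.allele_counts, cohort.gene_models,
                        cohort.fetal_reference, cohort.cohort_of, cfg=QCConfig())
        report = phased_unphased_concordance(qc_res.passed, qc_res.m_per_sample)
        assert report["phased"] == set() and report["unphased"] == set()

    def test_single_snp_genes_cannot_disagree(self):
        # phase cannot change which base of a single SNP is higher
        df = counts_frame([(100, "maternal", 3, 40, "G1"),
                           (100, "paternal", 45, 2, "G2")])
        report = phased_unphased_concordance(df, {})
        assert report["symmetric_difference"] == set()

    def test_grid_includes_operating_point(self, strong_cohort_qc):
        cohort, qc_res = strong_cohort_qc
        grid = evaluate_phasing_grid(qc_res.passed, qc_res.m_per_sample)
        ops = grid[(grid["min_bias"] == 7.2) & (grid["min_depth"] == 5)]
        assert len(ops) == 1
        assert ops["fp_rate"].iloc[0] <= 0.02

    def test_matching_assignment_gives_zero_fp_everywhere(self, strong_cohort_qc):
        cohort, qc_res = strong_cohort_qc
        grid = evaluate_phasing_grid(qc_res.passed, qc_res.m_per_sample)
        assert (grid["fp_rate"] == 0).all()
        assert (grid["true_calls"] > 0).all()


def test_joint_rule_controls_false_calls_on_shallow_null():
    """The higher-allele construction is anti-conservative at low depth;
    the joint bias/depth/P rule still keeps false calls under 2% of genes."""
    false_rates = []
    for seed in range(40, 44):
        cohort = generate_cohort(null_config(seed=seed, n_genes=80,
                                             read_depth_mean=8.0))
        qc_res = run_qc(cohort.snps, cohort.allele_counts, cohort.gene_models,
                        cohort.fetal_reference, cohort.cohort_of, cfg=QCConfig())
        summaries = summarize_genes(assign_snp_reads(qc_res.passed),
                                    qc_res.m_per_sample)
        calls = call_extreme_ase(summaries)
        per_sample = calls.groupby(["subject_id", "tissue"])["is_extreme_ase"].agg(
            ["sum", "count"])
        false_rates.append((per_sample["sum"] / per_sample["count"]).mean())
    assert np.mean(false_rates) < 0.02
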