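"""QC filter cascade: boundaries, cohort-level rules, REF-bias removal."""

import numpy as np
import pandas as pd
import pytest

from aseloe.io import GeneModel
from aseloe.qc import (
    QCConfig, alt_spliced_mask, biased_mask, filter_common_biased_snps,
    filter_gene_categories, filter_gene_structure, filter_genotype_quality,
    filter_min_coverage, filter_positional, filter_common_ase_genes,
    flag_biased_snp, subject_biallelic_fraction,
)

CFG = QCConfig()


def snp_frame(**cols):
    n = max(len(v) for v in cols.values() if hasattr(v, "__len__")) if cols else 1
    base = {
        "subject_id": "s1", "tissue": "t1", "chrom": "chr1",
        "pos": list(range(100, 100 + 1000 * n, 1000))[:n],
        "ref": "A", "alt": "G", "gene_id": "G1", "gq": 99.0, "dna_ab": 0.5,
        "parental_origin": "unknown", "effect_class": "missense",
        "population_af": 0.1, "ref_reads": 10, "alt_reads": 10,
    }
    base.update(cols)
    return pd.DataFrame(base)


class TestGenotypeQuality:
    @pytest.mark.parametrize("gq,ab,fails", [
        (50, 0.2, False),   # inclusive bounds pass
        (50, 0.8, False),
        (49, 0.5, True),
        (99, 0.81, True),
        (99, 0.19, True),
    ])
    def test_boundaries(self, gq, ab, fails):
        out = filter_genotype_quality(snp_frame(gq=[float(gq)], dna_ab=[ab]), CFG)
        assert bool(out.iloc[0]) is fails

    def test_missing_fields_are_skipped_not_failed(self):
        out = filter_genotype_quality(
            snp_frame(gq=[np.nan], dna_ab=[np.nan]), CFG)
        assert not out.iloc[0]


class TestCoverage:
    @pytest.mark.parametrize("ref,alt,fails", [
        (5, 0, False),  # five reads suffice
        (2, 1, False),  # both alleles expressed
        (3, 0, True),
        (0, 0, True),
    ])
    def test_rules(self, ref, alt, fails):
        out = filter_min_coverage(snp_frame(ref_reads=[ref], alt_reads=[alt]), CFG)
        assert bool(out.iloc[0]) is fails


class TestPositional:
    def test_three_snps_within_window_all_fail_clustered(self):
        df = snp_frame(pos=[100, 110, 120])
        out = filter_positional(df, cfg=CFG)
        assert out["clustered"].all()

    def test_spread_snps_pass(self):
        df = snp_frame(pos=[100, 200, 300])
        out = filter_positional(df, cfg=CFG)
        assert not out["clustered"].any()

    @pytest.mark.parametrize("indel_pos,fails", [(131, False), (130, True)])
    def test_indel_window_boundary(self, indel_pos, fails):
        df = snp_frame(pos=[100])
        indels = pd.DataFrame({"subject_id": ["s1"], "chrom": ["chr1"], "pos": [indel_pos]})
        out = filter_positional(df, indels=indels, cfg=CFG)
        assert bool(out["near_indel"].iloc[0]) is fails

    def test_repeat_flag_consumed(self):
        df = snp_frame(pos=[100])
        df["flag_repeat_region"] = True
        assert filter_positional(df, cfg=CFG)["repeat_region"].iloc[0]


class TestBiasedSNP:
    @pytest.mark.parametrize("ref,alt,biased", [
        (36, 5, True),    # ratio exactly 7.2 at the boundary
        (35, 5, False),
        (20, 20, False),
        (4, 0, False),    # higher allele below 5 reads
        (5, 0, True),     # monoallelic with enough reads
    ])
    def test_operating_point(self, ref, alt, biased):
        assert flag_biased_snp(ref, alt, CFG) is biased
        assert bool(biased_mask(snp_frame(ref_reads=[ref], alt_reads=[alt]), CFG).iloc[0]) is biased

    def test_allele_symmetric(self):
        assert flag_biased_snp(5, 36, CFG) and flag_biased_snp(36, 5, CFG)


class TestCommonBiased:
    def _cohort_frame(self, n_biased, n_total, effect="missense"):
        rows = []
        for i in range(n_total):
            biased = i < n_biased
            rows.append({
                "subject_id": f"s{i}", "tissue": "t1", "chrom": "chr1", "pos": 500,
                "ref": "A", "alt": "G", "gene_id": "G1", "effect_class": effect,
                "ref_reads": 40 if biased else 20, "alt_reads": 0 if biased else 20,
            })
        return pd.DataFrame(rows)

    def test_three_of_six_fails(self):
        df = self._cohort_frame(3, 6)
        cohort_of = {f"s{i}": "case" for i in range(6)}
        assert filter_common_biased_snps(df, cohort_of, CFG).all()

    def test_two_of_four_passes_min_subjects(self):
        df = self._cohort_frame(2, 4)
        cohort_of = {f"s{i}": "case" for i in range(4)}
        assert not filter_common_biased_snps(df, cohort_of, CFG).any()

    def test_nonsense_variants_exempt(self):
        df = self._cohort_frame(5, 6, effect="nonsense")
        cohort_of = {f"s{i}": "case" for i in range(6)}
        assert not filter_common_biased_snps(df, cohort_of, CFG).any()

    def test_imprinted_genes_exempt(self):
        df = self._cohort_frame(5, 6)
        cohort_of = {f"s{i}": "case" for i in range(6)}
        out = filter_common_biased_snps(df, cohort_of, CFG, exempt_genes={"G1"})
        assert not out.any()

    def test_cohorts_assessed_separately(self):
        # 3/6 biased among cases only: fails even though pooled rate is 25%
        df = pd.concat([self._cohort_frame(3, 6),
                        self._cohort_frame(0, 6).assign(
                            subject_id=lambda d: "c" + d["subject_id"])],
                       ignore_index=True)
        cohort_of = {f"s{i}": "case" for i in range(6)}
        cohort_of.update({f"cs{i}": "control" for i in range(6)})
        assert filter_common_biased_snps(df, cohort_of, CFG).all()


GENES = [
    GeneModel("G1", "SYM1", "chr1", "+", exons=((1, 10_000, ("iso1", "iso2")),)),
    GeneModel("G2", "SYM2", "chr1", "+",
              exons=((1, 10_000, ("iso1", "iso2")), (20_000, 21_000, ("iso1",)),)),
]


class TestGeneStructure:
    def test_single_monoallelic_high_coverage_snp_fails(self):
        df = snp_frame(pos=[100], ref_reads=[25], alt_reads=[0])
        out = filter_gene_structure(df, GENES, CFG)
        assert out["single_snp_monoallelic"].iloc[0]

    def test_single_balanced_snp_passes(self):
        df = snp_frame(pos=[100], ref_reads=[25], alt_reads=[20])
        out = filter_gene_structure(df, GENES, CFG)
        assert not out.any(axis=None)

    def test_two_of_five_unexpressed_fails_misaligned(self):
        df = snp_frame(pos=[100, 1100, 2100, 3100, 4100],
                       ref_reads=[10, 10, 10, 0, 0], alt_reads=[10, 10, 10, 0, 0],
                       effect_class=["UTR_3"] * 5)
        out = filter_gene_structure(df, GENES, CFG)
        assert out["misaligned"].all()

    def test_unexpressed_coding_snp_fails_misaligned(self):
        df = snp_frame(pos=[100, 1100, 2100, 3100, 4100, 5100],
                       ref_reads=[10] * 5 + [0], alt_reads=[10] * 5 + [0],
                       effect_class=["UTR_3"] * 5 + ["missense"])
        out = filter_gene_structure(df, GENES, CFG)
        assert out["misaligned"].all()

    def test_alt_spliced_exon_snp_flagged(self):
        df = snp_frame(pos=[100, 20_500], gene_id=["G2", "G2"])
        mask = alt_spliced_mask(df, GENES)
        assert mask.tolist() == [False, True]


class TestGeneCategories:
    def test_category_rules(self):
        genes = [
            GeneModel("GX", "S1", "chrX", "+", exons=((1, 10, ("i",)),)),
            GeneModel("GH", "HLA-B", "chr6", "+", exons=((1, 10, ("i",)),)),
            GeneModel("GN", "S3", "chr2", "+", exons=((1, 10, ("i",)),), coding_flag=False),
            GeneModel("GB", "S4", "chr3", "+", exons=((1, 10, ("i",)),)),
            GeneModel("GL", "S5", "chr4", "+", exons=((1, 10, ("i",)),)),
        ]
        fetal = pd.Series({"GX": 10.0, "GH": 10.0, "GN": 10.0, "GB": 2.0, "GL": 1.9})
        out = filter_gene_categories(genes, fetal, CFG)
        assert out.loc["GX", "fail"] and out.loc["GX", "sex_chromosome"]
        assert out.loc["GH", "hla"]
        assert out.loc["GN", "noncoding"]
        assert not out.loc["GB", "fail"]  # fetal r.p.m. exactly 2 passes
        assert out.loc["GL", "low_fetal_expression"]

    def test_common_ase_needs_a_control_subject(self):
        cohort_of = {f"s{i}": "case" for i in range(10)}
        cohort_of.update({f"c{i}": "control" for i in range(10)})
        # 6% of subjects, but all cases: kept
        only_cases = {"G1": {"s1"}, "G2": {"s1", "s2"}}
        assert filter_common_ase_genes(only_cases, 20, cohort_of, CFG) == set()
        # same fraction including one control: removed
        with_control = {"G2": {"s1", "c1"}}
        assert filter_common_ase_genes(with_control, 20, cohort_of, CFG) == {"G2"}


class TestSubjectQC:
    def _frame(self, n_biased, n_total):
        return snp_frame(
            pos=list(range(100, 100 + 1000 * n_total, 1000)),
            ref_reads=[40] * n_biased + [20] * (n_total - n_biased),
            alt_reads=[0] * n_biased + [20] * (n_total - n_biased),
        )

    def test_all_balanced_keeps_subject(self):
        out = subject_biallelic_fraction(self._frame(0, 10), GENES, CFG)
        assert out["fraction"].iloc[0] == 1.0
        assert out["verdict"].iloc[0] == "keep"

    def test_seven_of_ten_excluded(self):
        out = subject_biallelic_fraction(self._frame(3, 10), GENES, CFG)
        assert out["fraction"].iloc[0] == pytest.approx(0.70)
        assert out["verdict"].iloc[0] == "exclude"

    def test_expected_ase_snps_ignored(self):
        # biased SNPs on an imprinted gene do not count against the subject
        df = self._frame(3, 10)
        genes = [GeneModel("G1", "S", "chr1", "+", exons=((1, 100_000, ("i",)),),
                           known_imprinted="paternal")]
        out = subject_biallelic_fraction(df, genes, CFG)
        assert out.empty or out["n_snps"].iloc[0] == 0

    def test_null_subject_fraction_high(self, study_cohort):
        clean, _ = study_cohort
        merged = clean.allele_counts.merge(
            clean.snps, on=["subject_id", "chrom", "pos", "ref", "alt"])
        out = subject_biallelic_fraction(merged, clean.gene_models, CFG)
        # binomial tail mass beyond ratio 7.2 at p=0.5, depth ~60 is negligible;
        # injected events barely move per-subject fractions
        assert (out["fraction"] >= 0.95).all()


class TestCascade:
    def test_filters_never_modify_counts(self, study_cohort, study_qc):
        _, contaminated = study_cohort
        merged = contaminated.allele_counts.merge(
            contaminated.snps, on=["subject_id", "chrom", "pos", "ref", "alt"])
        assert study_qc.records["ref_reads"].sum() == merged["ref_reads"].sum()
        assert study_qc.records["alt_reads"].sum() == merged["alt_reads"].sum()

    def test_failed_filters_are_auditable(self, study_qc):
        failed = study_qc.records[study_qc.records["failed_filters"] != ""]
        assert len(failed) > 0
        names = set(",".join(failed["failed_filters"]).split(","))
        assert names <= set(study_qc.filter_order)
        passed_keys = len(study_qc.passed)
        assert passed_keys == (study_qc.records["failed_filters"] == "").sum()

    def test_contaminated_snps_removed_by_cascade(self, study_cohort, study_qc):
        _, contaminated = study_cohort
        contam = contaminated.truth["contaminated"]
        flagged = contam[contam["flagged"]]
        keys = set(map(tuple, flagged[["subject_id", "chrom", "pos"]].to_numpy()))
        surviving = set(map(tuple, study_qc.passed[["subject_id", "chrom", "pos"]].to_numpy()))
        assert not keys & surviving

    def test_ref_bias_removed_by_qc(self, study_cohort, study_qc):
        _, contaminated = study_cohort
        merged = contaminated.allele_counts.merge(
            contaminated.snps, on=["subject_id", "chrom", "pos", "ref", "alt"])
        pre = merged[biased_mask(merged, CFG)]
        pre_share = (pre["ref_reads"] > pre["alt_reads"]).mean()
        post = study_qc.passed[biased_mask(study_qc.passed, CFG)]
        post_share = (post["ref_reads"] > post["alt_reads"]).mean()
        assert pre_share > 0.75
        assert 0.4 <= post_share <= 0.6
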