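"""Star-allele diplotype calling and phenotype translation."""

import itertools

import pandas as pd
import pytest

from statinpgx import pgx
from statinpgx.pgx.translate import _cyp3a5_genotype_label

from conftest import make_calls


class TestImputation:
    def test_missing_call_becomes_reference_and_is_flagged(self, defs):
        calls = make_calls({}, defs)
        calls.loc[calls.rsid == "rs776746", ["allele1", "allele2"]] = "."
        out = pgx.impute_missing(calls, defs)
        rec = out[out.rsid == "rs776746"].iloc[0]
        assert (rec.allele1, rec.allele2) == ("A", "A")
        assert rec.imputed
        a = pgx.assign_phenotype("CYP3A5", out, defs)
        assert "rs776746" in a.imputed_calls
        assert a.diplotype == "*1/*1"

    def test_amplification_failure_marker_treated_as_missing(self, defs):
        calls = make_calls({}, defs)
        calls.loc[calls.rsid == "rs4149056", ["allele1", "allele2"]] = "fail"
        out = pgx.impute_missing(calls, defs)
        rec = out[out.rsid == "rs4149056"].iloc[0]
        assert (rec.allele1, rec.allele2) == ("T", "T") and rec.imputed

    def test_absent_variant_rows_are_added(self, defs):
        calls = make_calls({}, defs)
        calls = calls[calls.rsid != "rs4244285"]
        out = pgx.impute_missing(calls, defs)
        rec = out[out.rsid == "rs4244285"].iloc[0]
        assert rec.imputed and rec.allele1 == "G"

    def test_complete_calls_unchanged(self, defs):
        calls = make_calls({"rs4149056": 1}, defs)
        out = pgx.impute_missing(calls, defs)
        assert not out["imputed"].any()
        merged = calls.merge(out, on=["subject_id", "gene", "rsid"])
        assert (merged["allele1_x"] == merged["allele1_y"]).all()

    def test_idempotent(self, defs):
        calls = make_calls({"rs776746": 2}, defs)
        calls.loc[calls.rsid == "rs1045642", ["allele1", "allele2"]] = "."
        once = pgx.impute_missing(calls, defs)
        twice = pgx.impute_missing(once, defs)
        pd.testing.assert_frame_equal(
            once.sort_values(["subject_id", "rsid"]).reset_index(drop=True),
            twice.sort_values(["subject_id", "rsid"]).reset_index(drop=True))

    def test_unknown_rsid_rejected_by_name(self, defs):
        calls = make_calls({}, defs)
        calls.loc[0, "rsid"] = "rs999999"
        with pytest.raises(ValueError, match="rs999999"):
            pgx.impute_missing(calls, defs)


class TestDiplotypes:
    @pytest.mark.parametrize("copies,expected", [
        (0, "*1/*1"), (1, "*1/*5"), (2, "*5/*5"),
    ])
    def test_slco1b1_rs4149056_star5(self, defs, copies, expected):
        calls = make_calls({"rs4149056": copies}, defs)
        dip, flags = pgx.call_diplotype("SLCO1B1", calls, defs)
        assert dip == expected and not flags

    def test_cyp3a5_star1_is_absence_of_star3_and_star6(self, defs):
        calls = make_calls({}, defs)
        dip, _ = pgx.call_diplotype("CYP3A5", calls, defs)
        assert dip == "*1/*1"

    def test_trans_phasing_of_two_heterozygous_alleles(self, defs):
        calls = make_calls({"rs4244285": 1, "rs12248560": 1}, defs)
        dip, flags = pgx.call_diplotype("CYP2C19", calls, defs)
        assert dip == "*2/*17" and not flags

    def test_excess_variant_copies_keep_most_deleterious(self, defs):
        calls = make_calls({"rs4244285": 2, "rs12248560": 1}, defs)
        dip, flags = pgx.call_diplotype("CYP2C19", calls, defs)
        assert dip == "*2/*2"
        assert "excess_variant_alleles" in flags


class TestPhenotypes:
    @pytest.mark.parametrize("copies,phen", [(0, "NF"), (1, "DF"), (2, "PF")])
    def test_slco1b1_function_classes(self, defs, copies, phen):
        calls = make_calls({"rs4149056": copies}, defs)
        assert pgx.assign_phenotype("SLCO1B1", calls, defs).phenotype == phen

    def test_slco1b1_star1b_is_normal_function(self, defs):
        calls = make_calls({"rs2306283": 2}, defs)
        a = pgx.assign_phenotype("SLCO1B1", calls, defs)
        assert a.diplotype == "*1B/*1B" and a.phenotype == "NF"

    def test_slco1b1_severity_monotone_in_star5_dose(self, defs):
        rank = {"NF": 0, "DF": 1, "PF": 2}
        phens = [pgx.assign_phenotype(
            "SLCO1B1", make_calls({"rs4149056": k}, defs), defs).phenotype
            for k in (0, 1, 2)]
        assert rank[phens[0]] < rank[phens[1]] < rank[phens[2]]

    @pytest.mark.parametrize("copies,cn,score,phen", [
        ({"rs3892097": 2}, None, 0.0, "PM"),       # two no-function alleles
        ({}, 2, 2.0, "NM"),
        ({}, 0, 0.0, "PM"),                        # whole-gene deletion
        ({}, 3, 3.0, "UM"),
        ({"rs28371725": 1}, None, 1.5, "NM"),
        ({"rs1065852": 2}, None, 0.5, "IM"),
    ])
    def test_cyp2d6_activity_score(self, defs, copies, cn, score, phen):
        calls = make_calls(copies, defs)
        a = pgx.assign_phenotype("CYP2D6", calls, defs, copy_number=cn)
        assert a.activity_score == pytest.approx(score)
        assert a.phenotype == phen

    def test_cyp3a5_expresser_labels(self, defs):
        assert _cyp3a5_genotype_label("*1/*1") == "*1/*1"
        assert _cyp3a5_genotype_label("*1/*6") == "*1/*3"
        assert _cyp3a5_genotype_label("*3/*6") == "*3/*3"

    @pytest.mark.parametrize("copies,label", [
        ({}, "wild-type"),
        ({"rs1045642": 1}, "heterozygous"),
        ({"rs1045642": 2}, "mutant"),               # one hom-alt site
        ({"rs1045642": 1, "rs1128503": 1}, "mutant"),
    ])
    def test_transporter_merge_rule(self, defs, copies, label):
        calls = make_calls(copies, defs)
        assert pgx.merge_transporter_haplotype("ABCB1", calls, defs) == label

    def test_abcb1_core_subset_ignores_other_sites(self, defs):
        calls = make_calls({"rs3842": 2}, defs)
        assert pgx.merge_transporter_haplotype("ABCB1", calls, defs) == "mutant"
        assert pgx.merge_transporter_haplotype(
            "ABCB1", calls, defs, subset_rsids=pgx.ABCB1_CORE_RSIDS) == "wild-type"

    def test_ugt2b7_nucleotide_is_ground_truth_star_is_alias(self, defs):
        wide, _ = pgx.translate_cohort(make_calls({"rs7439366": 1}, defs))
        row = wide.iloc[0]
        assert row["ugt2b7_nt"] == "TC" and row["ugt2b7"] == "*1/*2"


class TestExhaustiveness:
    """Every combination of panel calls maps to exactly one phenotype."""

    @pytest.mark.parametrize("gene", ["SLCO1B1", "CYP3A5", "CYP2C19",
                                      "CYP2B6", "CYP2C9", "CYP1A2",
                                      "SLC22A1", "ABCB1", "UGT2B7"])
    def test_all_call_combinations_assign_one_label(self, defs, gene):
        rsids = defs.gene_rsids(gene, phenotype_only=True)
        for combo in itertools.product((0, 1, 2), repeat=len(rsids)):
            calls = make_calls(dict(zip(rsids, combo)), defs)
            a = pgx.assign_phenotype(gene, calls, defs)
            assert isinstance(a.phenotype, str) and a.phenotype

    @pytest.mark.parametrize("cn", [0, 1, 2, 3])
    def test_cyp2d6_combinations_with_copy_number(self, defs, cn):
        rsids = defs.gene_rsids("CYP2D6", phenotype_only=True)
        for combo in itertools.product((0, 1, 2), repeat=len(rsids)):
            calls = make_calls(dict(zip(rsids, combo)), defs)
            a = pgx.assign_phenotype("CYP2D6", calls, defs, copy_number=cn)
            assert a.phenotype in {"PM", "IM", "NM", "UM"}


class TestCohortTranslation:
    def test_fast_cohort_path_agrees_with_per_subject_assignment(
            self, defs, small_cohort):
        wide, long = pgx.translate_cohort(small_cohort.genotypes_true,
                                          small_cohort.cyp2d6_cn)
        calls = pgx.impute_missing(small_cohort.genotypes_true, defs)
        for sid in list(wide.index)[:8]:
            sub = calls[calls.subject_id == sid]
            cn = int(small_cohort.cyp2d6_cn.loc[sid])
            for gene, col in [("SLCO1B1", "slco1b1_phenotype"),
                              ("CYP2C19", "cyp2c19_phenotype"),
                              ("SLC22A1", "slc22a1_haplotype")]:
                a = pgx.assign_phenotype(gene, sub, defs)
                assert a.phenotype == wide.loc[sid, col]
            a = pgx.assign_phenotype("CYP2D6", sub, defs, copy_number=cn)
            assert a.phenotype == wide.loc[sid, "cyp2d6_phenotype"]

    def test_long_table_covers_every_subject_gene_pair(self, defs, small_cohort):
        _, long = pgx.translate_cohort(small_cohort.genotypes_true,
                                       small_cohort.cyp2d6_cn)
        assert len(long) == small_cohort.subjects.shape[0] * len(defs.genes)
        assert not long[["subject_id", "gene"]].duplicated().any()
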