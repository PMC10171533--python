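"""Reading, writing, harmonisation and QC of summary statistics."""
import numpy as np
import pandas as pd
import pytest

from genomicpca.errors import ConfigurationError, EmptyInputError
from genomicpca.sumstats import (harmonize, qc_filter, read_ldscores,
                                 read_sumstats, write_ldscores,
                                 write_sumstats)
from genomicpca.sumstats import LdScoreTable

from conftest import build_table


def _write(tmp_path, text, name="ss.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadSumstats:
    def test_z_backfilled_from_beta_se(self, tmp_path):
        p = _write(tmp_path, "SNP CHR BP A1 A2 EAF BETA SE N\n"
                             "rs1 1 100 A G 0.3 0.10 0.05 1000\n"
                             "rs2 1 200 C T 0.5 0.0 0.1 1000\n")
        t = read_sumstats(p)
        assert t.n_variants == 2
        assert t.df.loc[0, "z"] == pytest.approx(2.0)
        assert t.df.loc[1, "z"] == 0.0  # zero effect gives exactly zero z

    def test_non_acgt_rows_dropped(self, tmp_path):
        rows = ["rs1 1 1 A G 0.3 0.1 0.05 1000",
                "rs2 1 2 I D 0.3 0.1 0.05 1000",
                "rs3 1 3 C T 0.4 0.1 0.05 1000",
                "rs4 1 4 D I 0.2 0.1 0.05 1000",
                "rs5 1 5 G A 0.1 0.1 0.05 1000"]
        p = _write(tmp_path, "SNP CHR BP A1 A2 EAF BETA SE N\n"
                   + "\n".join(rows) + "\n")
        t = read_sumstats(p)
        assert t.n_variants == 3
        assert list(t.variant_ids) == ["rs1", "rs3", "rs5"]

    def test_missing_mandatory_column_is_config_error(self, tmp_path):
        p = _write(tmp_path, "SNP A1 A2 EAF BETA SE N\n"
                             "rs1 A G 0.3 0.1 0.05 1000\n")
        with pytest.raises(ConfigurationError):
            read_sumstats(p)

    def test_column_map_resolves_nonstandard_headers(self, tmp_path):
        p = _write(tmp_path, "rsid chrom pos ea oa freq b sd z nobs\n"
                             "rs1 1 5 A G 0.3 0.1 0.05 2.0 1000\n")
        t = read_sumstats(p, column_map={
            "snp": "rsid", "chrom": "chrom", "bp": "pos", "a1": "ea",
            "a2": "oa", "eaf": "freq", "beta": "b", "se": "sd", "z": "z",
            "n": "nobs"})
        assert t.n_variants == 1

    def test_all_rows_invalid_is_empty_input(self, tmp_path):
        p = _write(tmp_path, "SNP CHR BP A1 A2 EAF BETA SE N\n"
                             "rs1 1 1 I D 0.3 0.1 0.05 1000\n")
        with pytest.raises(EmptyInputError):
            read_sumstats(p)

    def test_roundtrip_preserves_numeric_fields(self, tmp_path,
                                                four_variant_table):
        path = tmp_path / "rt.tsv"
        write_sumstats(four_variant_table, path)
        back = read_sumstats(path, trait_label="vol1")
        for col in ("eaf", "beta", "se", "z"):
            np.testing.assert_allclose(back.df[col], four_variant_table.df[col],
                                       rtol=1e-12)
        assert (back.df["n"] == four_variant_table.df["n"]).all()


class TestLdScoreIo:
    def test_roundtrip_with_m_sidecar(self, tmp_path):
        ld = LdScoreTable(pd.DataFrame({"snp": ["rs1", "rs2"],
                                        "l2": [1.5, 3.25]}), m_total=5000)
        p = tmp_path / "scores.l2.ldscore"
        write_ldscores(ld, p)
        back = read_ldscores(p)
        assert back.m_total == 5000
        np.testing.assert_allclose(back.df["l2"], ld.df["l2"], rtol=1e-12)

    def test_missing_m_sidecar_is_config_error(self, tmp_path):
        p = _write(tmp_path, "SNP\tL2\nrs1\t1.0\n", name="x.ldscore")
        with pytest.raises(ConfigurationError):
            read_ldscores(p)


def _ref():
    return build_table(
        trait="ref", snps=["rs1", "rs2", "rs3"],
        a1=["A", "C", "A"], a2=["G", "T", "T"],
        eaf=[0.3, 0.4, 0.2], beta=[0.1, 0.2, 0.05], se=[0.05, 0.1, 0.05])


class TestHarmonize:
    def test_identical_table_unchanged(self):
        ref = _ref()
        out, rep = harmonize([ref.copy()], ref)
        assert rep.n_flipped == 0
        assert rep.n_kept == 3
        np.testing.assert_allclose(out[0].df["beta"], ref.df["beta"])

    def test_swapped_alleles_flip_sign_and_frequency(self):
        ref = _ref()
        t = build_table(trait="t", snps=["rs1"], a1=["G"], a2=["A"],
                        eaf=[0.3], beta=[0.2], se=[0.1])
        out, rep = harmonize([t], ref)
        assert rep.n_flipped == 1
        assert out[0].df.loc[0, "beta"] == pytest.approx(-0.2)
        assert out[0].df.loc[0, "eaf"] == pytest.approx(0.7)
        assert out[0].df.loc[0, "a1"] == "A"

    def test_palindromic_dropped_under_drop_policy(self):
        ref = _ref()
        t = ref.copy()
        out, rep = harmonize([t], ref, ambiguous_policy="drop")
        # rs3 is A/T (palindromic): dropped from every output
        assert rep.n_strand_dropped == 1
        assert "rs3" not in set(out[0].variant_ids)

    def test_high_maf_palindromic_dropped_under_freq_resolve(self):
        ref = build_table(trait="r", snps=["rs1"], a1=["A"], a2=["T"],
                          eaf=[0.45], beta=[0.1], se=[0.05])
        out, rep = harmonize([ref.copy()], ref, ambiguous_policy="freq_resolve")
        assert rep.n_strand_dropped == 1
        assert rep.n_kept == 0

    def test_irreconcilable_alleles_counted_not_kept(self):
        ref = _ref()
        t = build_table(trait="t", snps=["rs1"], a1=["A"], a2=["C"],
                        eaf=[0.3], beta=[0.2], se=[0.1])
        out, rep = harmonize([t], ref)
        assert out[0].n_variants == 0
        assert rep.n_missing_dropped == 3  # rs1 irreconcilable, rs2/rs3 absent
        assert rep.n_kept + rep.n_strand_dropped + rep.n_missing_dropped == 3

    def test_idempotent(self):
        ref = _ref()
        t = build_table(trait="t", snps=["rs2", "rs1"], a1=["T", "G"],
                        a2=["C", "A"], eaf=[0.6, 0.7], beta=[0.3, 0.2],
                        se=[0.1, 0.1])
        once, _ = harmonize([t], ref)
        twice, rep2 = harmonize(once, ref)
        assert rep2.n_flipped == 0
        pd.testing.assert_frame_equal(once[0].df, twice[0].df)

    def test_flip_is_an_involution(self):
        ref = _ref()
        flipped = ref.copy()
        flipped.df["a1"], flipped.df["a2"] = (ref.df["a2"].copy(),
                                              ref.df["a1"].copy())
        flipped.df["beta"] = -flipped.df["beta"]
        flipped.df["z"] = -flipped.df["z"]
        flipped.df["eaf"] = 1 - flipped.df["eaf"]
        out, _ = harmonize([flipped], ref)
        sub = out[0].df.set_index("snp")
        orig = ref.df.set_index("snp").loc[sub.index]
        np.testing.assert_allclose(sub["beta"], orig["beta"], atol=1e-15)
        np.testing.assert_allclose(sub["eaf"], orig["eaf"], atol=1e-15)

    def test_outputs_share_one_ordered_variant_frame(self):
        ref = _ref()
        t1 = ref.copy()
        t2 = build_table(trait="b", snps=["rs3", "rs1"], a1=["A", "A"],
                         a2=["T", "G"], eaf=[0.2, 0.3], beta=[0.1, 0.1],
                         se=[0.1, 0.1])
        out, _ = harmonize([t1, t2], ref)
        assert list(out[0].variant_ids) == list(out[1].variant_ids)


class TestQcFilter:
    def test_maf_threshold(self):
        t = build_table(trait="t", snps=["rs1", "rs2", "rs3", "rs4"],
                        a1=["A"] * 4, a2=["G"] * 4,
                        eaf=[0.001, 0.02, 0.2, 0.4],
                        beta=[0.1] * 4, se=[0.1] * 4)
        out = qc_filter(t, min_maf=0.01, chisq_cap_rule="none")
        assert out.n_variants == 3

    def test_noop_filters_are_identity(self, four_variant_table):
        out = qc_filter(four_variant_table, min_maf=0.0, chisq_cap_rule="none")
        pd.testing.assert_frame_equal(out.df, four_variant_table.df)

    def test_chisq_cap_removes_extreme_statistics(self):
        t = build_table(trait="t", snps=["rs1", "rs2"], a1=["A", "C"],
                        a2=["G", "T"], eaf=[0.3, 0.3],
                        z=[10.0, 2.0], n=[10_000, 10_000])
        out = qc_filter(t, min_maf=0.0, chisq_cap_rule="ldsc_default")
        # z^2 = 100 > max(80, 0.001 * 10000) = 80 -> dropped
        assert list(out.variant_ids) == ["rs2"]

    def test_input_not_mutated(self, four_variant_table):
        before = four_variant_table.df.copy()
        qc_filter(four_variant_table, min_maf=0.1)
        pd.testing.assert_frame_equal(four_variant_table.df, before)

    def test_all_removed_is_empty_output_error(self):
        t = build_table(trait="t", snps=["rs1", "rs2"], a1=["A", "C"],
                        a2=["G", "T"], eaf=[0.1, 0.2],
                        beta=[0.1, 0.1], se=[0.1, 0.1])
        with pytest.raises(EmptyInputError):
            qc_filter(t, min_maf=0.3)
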