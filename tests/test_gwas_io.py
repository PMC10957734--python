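"""I/O and harmonization behaviour, including the palindrome rule table."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrkit import (FormatError, HarmonizationError, harmonize,
                   read_summary_table, to_odds_ratio, write_summary_table)


def _table(rows):
    """Rows: (snp_id, ea, oa, eaf, beta, se, pval)."""
    return pd.DataFrame(
        rows, columns=["snp_id", "effect_allele", "other_allele",
                       "eaf", "beta", "se", "pval"])


class TestReadWrite:
    def test_well_formed_table_is_fully_loaded(self, summary_tsv):
        table, report = read_summary_table(summary_tsv)
        assert len(table) == 3
        assert report.drop_count == 0
        assert list(table["snp_id"]) == ["rs1", "rs2", "rs3"]
        assert table["n"].iloc[0] == 100000

    def test_invalid_rows_are_dropped_and_counted(self):
        text = ("SNP\teffect_allele\tother_allele\tbeta\tse\tpval\n"
                "rs1\ta\tg\t0.1\t0.01\t0.5\n"
                "rs2\tA\tG\t0.1\t0.0\t0.5\n"      # se = 0
                "rs3\tA\tG\t0.1\t0.01\t1.5\n"      # pval > 1
                "rs4\tAT\tG\t0.1\t0.01\t0.5\n")    # indel
        table, report = read_summary_table(io.StringIO(text))
        assert len(table) == 1
        assert report.drop_count == 3
        assert report.drop_reasons["nonpositive_se"] == 1
        assert table["effect_allele"].iloc[0] == "A"  # upper-cased

    def test_header_matching_is_case_insensitive(self):
        text = "snp\tEffect_Allele\tOTHER_ALLELE\tBeta\tSE\tPval\nrs1\tA\tG\t0.1\t0.01\t0.5\n"
        table, _ = read_summary_table(io.StringIO(text))
        assert list(table["snp_id"]) == ["rs1"]

    def test_missing_mandatory_column_is_named(self):
        text = "SNP\teffect_allele\tbeta\tse\tpval\nrs1\tA\t0.1\t0.01\t0.5\n"
        with pytest.raises(FormatError, match="other_allele"):
            read_summary_table(io.StringIO(text))

    def test_empty_table_is_an_error(self):
        text = "SNP\teffect_allele\tother_allele\tbeta\tse\tpval\n"
        with pytest.raises(FormatError, match="empty"):
            read_summary_table(io.StringIO(text))

    def test_round_trip_is_lossless(self, small_study):
        sink = io.StringIO()
        write_summary_table(small_study.exposure_stats, sink)
        sink.seek(0)
        again, report = read_summary_table(sink)
        assert report.drop_count == 0
        np.testing.assert_allclose(again["beta"], small_study.exposure_stats["beta"],
                                   rtol=1e-9)
        assert list(again["snp_id"]) == list(small_study.exposure_stats["snp_id"])
        # canonical 10-significant-digit formatting makes a second pass byte-identical
        sink2 = io.StringIO()
        write_summary_table(again, sink2)
        assert sink.getvalue() == sink2.getvalue()

    def test_empty_record_list_writes_header_only(self):
        sink = io.StringIO()
        write_summary_table(pd.DataFrame(columns=["snp_id"]), sink)
        lines = sink.getvalue().strip().split("\n")
        assert len(lines) == 1 and lines[0].startswith("snp_id\t")


class TestHarmonize:
    def test_swapped_alleles_flip_the_outcome_beta(self):
        exp = _table([("rs1", "A", "G", 0.2, 0.1, 0.01, 1e-9)])
        out = _table([("rs1", "G", "A", 0.8, -0.05, 0.01, 1e-3)])
        h = harmonize(exp, out)
        assert h.audit["action"].iloc[0] == "allele_flipped"
        assert h.data["beta_outcome"].iloc[0] == pytest.approx(0.05)

    def test_strand_complement_is_reconciled(self):
        exp = _table([("rs1", "A", "G", 0.2, 0.1, 0.01, 1e-9)])
        out = _table([("rs1", "T", "C", 0.2, 0.07, 0.01, 1e-3)])  # same SNP, other strand
        h = harmonize(exp, out)
        assert h.n_snps == 1
        assert h.data["beta_outcome"].iloc[0] == pytest.approx(0.07)

    def test_irreconcilable_alleles_are_dropped(self):
        exp = _table([("rs1", "A", "G", 0.2, 0.1, 0.01, 1e-9),
                      ("rs2", "A", "G", 0.2, 0.1, 0.01, 1e-9)])
        out = _table([("rs1", "A", "C", 0.2, 0.1, 0.01, 1e-3),
                      ("rs2", "A", "G", 0.2, 0.1, 0.01, 1e-3)])
        h = harmonize(exp, out)
        assert h.n_snps == 1
        assert dict(zip(h.audit["snp_id"], h.audit["action"]))["rs1"] == "incompatible_dropped"

    @pytest.mark.parametrize("eaf_exp,eaf_out,kept", [
        (0.50, 0.50, False),   # maximally ambiguous
        (0.10, 0.10, True),    # clearly below threshold on both sides
        (0.90, 0.90, True),    # clearly above
        (0.10, 0.90, False),   # discordant sides -> ambiguous strand
        (0.45, 0.45, False),   # inside the ambiguity band
    ])
    def test_palindromic_conservative_rule(self, eaf_exp, eaf_out, kept):
        exp = _table([("rs1", "A", "T", eaf_exp, 0.1, 0.01, 1e-9)])
        out = _table([("rs1", "A", "T", eaf_out, 0.05, 0.01, 1e-3)])
        h = harmonize(exp, out, palindrome_policy="conservative", eaf_threshold=0.42)
        action = h.audit["action"].iloc[0]
        assert (action == "palindromic_kept") == kept

    def test_palindromic_drop_policy_always_drops(self):
        exp = _table([("rs1", "A", "T", 0.1, 0.1, 0.01, 1e-9)])
        out = _table([("rs1", "A", "T", 0.1, 0.05, 0.01, 1e-3)])
        h = harmonize(exp, out, palindrome_policy="drop")
        assert h.n_snps == 0
        assert h.audit["action"].iloc[0] == "palindromic_dropped"

    def test_empty_intersection_raises(self):
        exp = _table([("rs1", "A", "G", 0.2, 0.1, 0.01, 1e-9)])
        out = _table([("rs2", "A", "G", 0.2, 0.1, 0.01, 1e-3)])
        with pytest.raises(HarmonizationError):
            harmonize(exp, out)

    def test_idempotence_on_aligned_data(self, small_study):
        h1 = harmonize(small_study.exposure_stats, small_study.outcome_stats)
        # rebuild an outcome table already aligned to the exposure
        kept = small_study.exposure_stats[
            small_study.exposure_stats["snp_id"].isin(h1.data["snp_id"])].copy()
        aligned = kept.copy()
        aligned["beta"] = h1.data.set_index("snp_id").loc[aligned["snp_id"], "beta_outcome"].to_numpy()
        aligned["se"] = h1.data.set_index("snp_id").loc[aligned["snp_id"], "se_outcome"].to_numpy()
        h2 = harmonize(kept, aligned)
        np.testing.assert_allclose(h2.data["beta_outcome"], h1.data["beta_outcome"])
        assert set(h2.audit["action"]) <= {"kept", "palindromic_kept"}

    def test_sign_equivariance(self, small_study):
        """Flipping every outcome record's alleles and beta changes nothing."""
        out = small_study.outcome_stats
        flipped = out.copy()
        flipped["effect_allele"], flipped["other_allele"] = (
            out["other_allele"].copy(), out["effect_allele"].copy())
        flipped["beta"] = -out["beta"]
        flipped["eaf"] = 1.0 - out["eaf"]
        h1 = harmonize(small_study.exposure_stats, out)
        h2 = harmonize(small_study.exposure_stats, flipped)
        pd.testing.assert_frame_equal(h1.data, h2.data)

    def test_audit_conserves_every_shared_snp(self, small_study):
        h = harmonize(small_study.exposure_stats, small_study.outcome_stats)
        counts = h.action_counts()
        assert sum(counts.values()) == len(small_study.exposure_stats)
        assert (counts["kept"] + counts["allele_flipped"]
                + counts["palindromic_kept"]) == h.n_snps


class TestOddsRatio:
    def test_null_beta(self):
        res = to_odds_ratio(0.0, 0.1, 0.95)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(np.exp(-stats.norm.ppf(0.975) * 0.1))
        assert (round(res.ci_low, 3), round(res.ci_high, 3)) == (0.822, 1.217)

    def test_published_scale_consistency(self):
        # log(1.17) with the SE back-solved from a 1.087-1.26 interval
        res = to_odds_ratio(0.157, 0.0377, 0.95)
        assert res.odds_ratio == pytest.approx(1.17, abs=0.005)
        assert res.ci_low == pytest.approx(1.087, abs=0.005)
        assert res.ci_high == pytest.approx(1.26, abs=0.01)

    def test_zero_se_degenerates_to_point(self):
        res = to_odds_ratio(0.3, 0.0)
        assert res.ci_low == res.odds_ratio == res.ci_high

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            to_odds_ratio(0.1, 0.1, level=1.5)
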